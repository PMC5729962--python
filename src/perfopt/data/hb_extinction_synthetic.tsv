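# Synthetic approximation of the standard compiled molar extinction spectra of
# oxy- and deoxyhemoglobin (base-10, M^-1 cm^-1), hand-built to reproduce the
# visible band structure: HbO2 double peak near 542/577 nm with the 560-nm dip,
# Hb single peak near 555 nm, isosbestic crossings near 500/547/571/583 nm, and
# Hb >> HbO2 above 600 nm. Adequate for simulation and self-consistent
# inversion; not a literature-accurate tabulation.
# source=synthetic compilation (this package)
wavelength_nm	eps_hbo2	eps_hb
450	62816	103292
460	44480	85000
470	33209	65000
480	27000	47000
490	23000	32000
500	20932	20862
505	21800	21000
510	24000	22000
515	27500	24000
520	31500	26500
525	36500	30000
530	40800	35000
535	47500	40000
540	53236	44500
545	52000	48500
550	45000	51500
555	37500	53412
560	32613	53788
565	35500	50000
570	44496	45072
575	54000	41000
580	50104	37020
585	31000	34000
590	14000	28000
595	6500	21000
600	3200	14677
610	1506	9443
620	942	6509
630	610	5149
640	442	4345
650	368	3750
660	320	3227
670	294	2795
680	278	2407
690	274	2051
700	290	1794
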