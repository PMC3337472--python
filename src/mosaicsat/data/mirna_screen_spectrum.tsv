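# Allele spectrum of a saturation F1 mosaic screen for miRNA-silencing genes
# on Drosophila chromosome arms 2R and 3R: 45 retained EMS/insertional
# mutations assigned by complementation testing to 24 loci.
# The nine molecularly identified genes carry 30 of the 45 alleles; the 15
# unidentified complementation groups therefore hold one allele each
# (45 - 30 = 15 mutations over 15 groups, necessarily all singletons).
locus_id	n_alleles
Drosha	3
Pasha	6
Dicer-1	8
Ago1	8
Bap55	1
Dcp-1	1
Domino	1
Grappa	1
Syndecan	1
group-10	1
group-11	1
group-12	1
group-13	1
group-14	1
group-15	1
group-16	1
group-17	1
group-18	1
group-19	1
group-20	1
group-21	1
group-22	1
group-23	1
group-24	1
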