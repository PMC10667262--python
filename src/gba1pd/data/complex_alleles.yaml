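# Named GBA1/GBAP1 recombinant alleles: all components must co-occur on one
# phased haplotype for the allele to be called.
complex_alleles:
  - name: RecNciI
    components: [p.L483P, p.A495P, p.V499V]
    severity: severe
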