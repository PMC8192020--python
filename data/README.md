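# Study data (not redistributed)

Two acceptance tests recompute published numbers from the original
study's supplementary files, which are not redistributable with this
package.  To run them, download the supplementary material of the study
this package emulates (the two-species ricefish introgression analysis)
and place:

- `study_snps.vcf` — the 1,552-SNP two-species VCF (supplementary SNP
  data used for the site frequency spectrum);
- `study_popmap.txt` — two columns: sample ID, species label (one line
  per VCF sample);
- `study_nd2.fasta` — the aligned 1,053-bp ND2 sequences (30
  individuals);
- `study_nd2_groups.txt` — two columns: sequence ID, haplogroup, using
  the labels `eversi`, `sarasinorum_eversi_like` and `sarasinorum` for
  the donor species' haplotypes, the donor-like haplotypes found in the
  recipient, and the recipient's main haplogroup respectively.

Without these files the two tests fail with a pointer to this README;
every other test is self-contained (synthetic data generated at run
time).
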