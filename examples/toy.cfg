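# Toy-scale synthetic study for a quick end-to-end run (~10 s).
# Keys are RunConfig fields; values override the defaults.
seed = 7
n_contigs = 6
contig_length = 12000
n_clusters = 3
cluster_size = 1500
n_b_contigs = 1
srna_reads = 8000
wgs_depth = 15.0
qpcr_n_perm = 2000
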