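# islandshift

Genomic island prediction in bacterial genomes by mean-shift clustering of
window nucleotide composition.

Genomic islands (GIs) are regions acquired by horizontal gene transfer;
they frequently carry pathogenicity, antibiotic-resistance and metabolic
genes, and — because donor and recipient usually differ in base
composition — they stand out compositionally from the host backbone.
`islandshift` partitions a genome into fixed-length windows, represents
each window by its (A, T, C, G) count vector, and clusters the vectors
with a from-scratch mean-shift procedure. Windows of alien composition
end up in low-mass clusters, which are reported as candidate islands.
The tool is aimed at microbial genomicists screening finished
chromosomes or plasmids (0.5–6 Mb) for horizontally acquired regions
without any annotation, alignment or reference panel.

## Method

Given window feature vectors x_i ∈ R⁴, the density at x is estimated with
a radially symmetric kernel K(x) = c_{k,d} k(‖x‖²):

    f̂(x) = 1/(n hᵈ) Σᵢ K((x − xᵢ)/h)

With g = −k′, each point is moved by the mean-shift vector

    m_h(x) = Σᵢ xᵢ g(‖(x − xᵢ)/h‖²) / Σᵢ g(‖(x − xᵢ)/h‖²) − x

until convergence; points reaching the same density mode form one
cluster. The number of clusters is a consequence of the bandwidth h, not
an input.

The bandwidth is tuned automatically by inserting artificial fragments:
window-sized slices of donor genomes whose nucleotide sums ΣYᵢ deviate
from the host statistics, ΣYᵢ < X̄ − cσ or ΣYᵢ > X̄ + cσ (c ≥ 1), and
which differ pairwise by more than 7.5% in the sum of their four
nucleotides. Starting from the host feature-space diameter, h is
decreased geometrically until every artificial fragment is clustered on
its own; at that h, genuinely alien host windows also separate from the
backbone. Finally, any cluster whose total window mass does not surpass
200 kb — regardless of whether its windows are consecutive — is called,
and each run of consecutive windows is reported as one island interval.

Defaults: 50 kb windows, 5 artificial fragments, c = 1, 200 kb mass cap.

## Worked example

Build a synthetic benchmark — a 2 Mb host at G+C 0.55 carrying a 150 kb
implant of G+C 0.30 at 0.8 Mb — plus a donor pool spanning G+C 0.25–0.75,
then run the predictor:

```python
from islandshift.synthetic import (island_benchmark_spec, generate_host,
                                   write_fasta, generate_donor_pool,
                                   DEFAULT_DONOR_GCS)
genome, truth = generate_host(island_benchmark_spec(seed=1))
write_fasta(genome, "example_host.fna")
generate_donor_pool(DEFAULT_DONOR_GCS, 500_000, 1, "donors")
print(truth)   # [(800000, 950000)]
```

```bash
islandshift --input example_host.fna --donor-dir donors --seed 1 --out-prefix demo
```

prints

```
# islandshift genomic island report
# genome: synthetic_host_gc0.55_seed1 (2.000 Mb)
# window_length: 50000
# n_fragments: 5
# std_coeff: 1.0
# max_island_mass: 200000
# kernel: gaussian
# epsilon: 0.001
# seed: 1
# h_init: 12823.838973
# bandwidth: 828.558737
# bandwidth_steps: 27
# fragments: [{'donor': 'synthetic_donor_gc0.35', 'offset': 250000}, ...]
identifier	interval_mb	start_bp	end_bp	mass_bp
GI01	0.800–0.950	800000	950000	150000
```

The search started at the host feature-space diameter (h_init ≈ 12824
count units), decayed ×0.9 for 27 steps, and settled at h ≈ 829, the
largest bandwidth at which all five artificial fragments sit in clusters
of their own. The final clustering of the 40 host windows then splits
into a 1.85 Mb backbone cluster and a 150 kb cluster — below the 200 kb
cap — reported as island GI01 at 0.800–0.950 Mb, exactly the implanted
interval. Alongside the report the run writes `demo.islands.bed`
(0-based half-open), `demo.clusters.tsv`, `demo.search.tsv`, `demo.log`,
and with `--plot` a cumulative-G+C curve with islands highlighted.

A homogeneous genome produces a single giant cluster and the report
states `no genomic islands detected`.

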