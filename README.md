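# introscan

Archaic-introgression analysis on haplotype-resolved genomes: detect
Neanderthal/Denisovan-derived tracts in modern human haplotypes, project
structural variants (SVs >= 50 bp) onto them, screen unalignable (e.g.
centromeric) sequence with archaic-specific k-mers, scan for adaptive
introgression, and date/quantify selection on introgressed alleles — all
testable end-to-end against a built-in synthetic-cohort generator with known
ground truth, so no external data is needed.

The package is aimed at population geneticists working with phased
assemblies or phased variant calls for a focal population (e.g. Papuan-like)
alongside an African-like outgroup, an East-Asian-like sister group, and
high-coverage archaic reference genomes.

## What it computes

- **`simgen`** — msprime-backed cohorts with admixture pulses and recorded
  introgression truth (census ancestry), donor-private tag alleles,
  implanted SVs, sweeps on existing alleles, alpha-satellite HOR arrays;
  FASTA/VCF/BED output with byte-identical round trips.
- **`archdetect`** — two-state Poisson HMM over windowed counts of private
  derived variants; Baum-Welch fitting, posterior decoding into segments,
  derived-allele match rates to each archaic genome, origin labels
  (NDL / DNS / AMB / REJECTED, with the <10% low-affinity rejection rule),
  consensus with external (e.g. Sprime) segment BEDs.
- **`svmap`** — SV merging by 50% reciprocal overlap (breakpoint+size rule
  for insertions), projection onto introgressed segments, per-genome
  introgressed INS/DEL base tallies, genic enrichment (one-sided Fisher +
  length-preserving permutation null), genotype concordance.
- **`kmerscan`** — canonical archaic-specific k-mers (present repeatedly in
  archaic inputs, absent from the outgroup), per-2-kbp window counts,
  count-cutoff calibration to the genome-wide introgression fraction,
  Mann-Whitney enrichment, and best-hit window identity
  (substitutions + indels) for satellite comparison.
- **`selscan`** — Hudson F_ST, PBS over 100-SNV segments and per SV, f_D,
  r²/D′, and empirical p-values from coalescent-simulated nulls computed
  through the same code path.
- **`timeinfer`** — pairwise-coalescent TMRCA posterior decoding and sweep
  scores, a Wright-Fisher frequency-grid likelihood for selection
  coefficients (single- and two-epoch, chi-squared LRT), Kimura-style
  alpha-satellite mutation-rate estimation mu = d/(2T/g + 4·N_anc), and
  QV ↔ error-rate conversion.

Key formulas: PBS = (T(F_fs) + T(F_fo) - T(F_so))/2 with T(x) = -ln(1-x);
Hudson F_ST = [(p1-p2)² - p1q1/(n1-1) - p2q2/(n2-1)] / [p1q2 + p2q1];
f_D = S(P1,P2,P3,O)/S(P1,P_D,P_D,O) with per-site donor proxy
P_D = argmax(p2, p3); TMRCA emission Poisson(2·mu·L·T_j);
QV = -10·log10(error).

## Worked example

```python
import numpy as np
from introscan import simgen, archdetect, selscan

model = simgen.papuan_model()          # AFR/EAS/PNG + NDL/DNS, two pulses
cohort = simgen.simulate_cohort(
    model, 2_000_000,
    {"AFR": 16, "EAS": 8, "PNG": 8, "NDL": 4, "DNS": 4},
    seed=2024,
)
print(f"truth: {100*cohort.introgressed_fraction('PNG'):.2f}% of PNG bases introgressed")

afr = [cohort.hap_index(h) for h in cohort.haplotypes_of("AFR")]
out_pos = cohort.variants["pos"].to_numpy()[cohort.genotypes[:, afr].any(axis=1)]
hap = cohort.haplotypes_of("PNG")[0]
obs = archdetect.window_private_variants(
    cohort.derived_positions(hap), out_pos, 1000, cohort.chrom_length)
params = archdetect.fit_hmm(obs)
segs = archdetect.decode_segments(obs, params, 0.8, haplotype=hap)
print(f"lambda_modern={params.rates[0]:.2f}, lambda_archaic={params.rates[1]:.2f}, "
      f"{len(segs)} segments on {hap}")

arch = {d: {"derived": cohort.variants['pos'].to_numpy()[
            cohort.genotypes[:, [cohort.hap_index(h)
            for h in cohort.haplotypes_of(d)]].any(axis=1)]}
        for d in ("NDL", "DNS")}
for seg in segs[:3]:
    seg.match_profile = archdetect.match_rate(
        seg, cohort.derived_positions(hap), arch, out_pos)
    seg.origin = archdetect.classify_origin(seg.match_profile)
    r = seg.match_profile.rates
    print(f"  {seg.start}-{seg.end}: NDL={r['NDL']:.2f} DNS={r['DNS']:.2f} -> {seg.origin}")
```

Output (seed 2024):

```
truth: 2.21% of PNG bases introgressed
lambda_modern=0.08, lambda_archaic=1.44, 7 segments on PNG1_hap1
  115000-119000: NDL=0.00 DNS=0.00 -> REJECTED
  807000-837000: NDL=0.95 DNS=0.29 -> NDL
  842000-871000: NDL=0.98 DNS=0.07 -> NDL
```

The fitted archaic emission rate (~1.4 private variants per kbp) reflects
the implanted donor-private tag density (1/kbp) plus archaic-branch
variants. The first segment matches neither archaic genome — a false
positive that the <10% low-affinity rule correctly rejects — while the
others match the Neanderthal reference at >95% of informative sites and
inherit the NDL label.

A CLI mirrors the main pipelines:

```sh
introscan simulate --length 1000000 --seed 7 --out cohort/
introscan detect --cohort cohort/ --out segments.tsv
introscan kmer build --archaic arch.fa --outgroup afr.fa --out kmers.txt
introscan time qv 44.5 --direction to_error
```

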