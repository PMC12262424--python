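"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

from introscan import simgen


@pytest.fixture(scope="session")
def papuan_cohort():
    """Two-pulse cohort (2 Mbp) with African/East-Asian panels and archaic
    reference samples; the workhorse for detection and projection tests."""
    return simgen.simulate_cohort(
        simgen.papuan_model(),
        2_000_000,
        {"AFR": 16, "EAS": 8, "PNG": 8, "NDL": 4, "DNS": 4},
        seed=2024,
    )


@pytest.fixture(scope="session")
def seq_cohort():
    """Small cohort with actual haplotype sequences, for k-mer tests."""
    return simgen.simulate_cohort(
        simgen.papuan_model(),
        500_000,
        {"AFR": 8, "EAS": 4, "PNG": 8, "NDL": 4, "DNS": 4},
        seed=77,
        with_sequences=True,
    )


@pytest.fixture(scope="session")
def archaic_kmer_set(seq_cohort):
    """Archaic-specific k-mers of the sequence cohort (k=31)."""
    from introscan import kmerscan

    coh = seq_cohort
    arch = [coh.sequences[(s, k)] for s in coh.samples for k in (1, 2)
            if coh.sample_population[s] in ("NDL", "DNS")]
    outg = [coh.sequences[(s, k)] for s in coh.samples for k in (1, 2)
            if coh.sample_population[s] == "AFR"]
    return kmerscan.build_archaic_specific_kmers(arch, outg, k=31)


def panel_positions(cohort, pop):
    """Positions where any haplotype of ``pop`` carries a derived allele."""
    idx = [cohort.hap_index(h) for h in cohort.haplotypes_of(pop)]
    has = cohort.genotypes[:, idx].any(axis=1)
    return cohort.variants["pos"].to_numpy()[has]


def archaic_panel(cohort):
    return {
        d: {"derived": panel_positions(cohort, d)}
        for d in ("NDL", "DNS")
        if cohort.haplotypes_of(d)
    }


def base_level_f1(cohort, hap, segments):
    """Base-level F1 of called segments against the haplotype's truth tracts."""
    call = np.zeros(cohort.chrom_length, dtype=bool)
    for s in segments:
        call[s.start : s.end] = True
    truth = np.zeros(cohort.chrom_length, dtype=bool)
    for _, row in cohort.tracts_of(hap).iterrows():
        truth[row["start"] : row["end"]] = True
    tp = int((call & truth).sum())
    fp = int((call & ~truth).sum())
    fn = int((~call & truth).sum())
    prec = tp / max(tp + fp, 1)
    rec = tp / max(tp + fn, 1)
    return 2 * prec * rec / max(prec + rec, 1e-12)
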