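"""Synthetic multi-population cohorts with known archaic-introgression truth.

This module emulates the data a long-read population study of archaic
admixture works from: phased haplotypes for an African-like outgroup, an
East-Asian-like sister group and a Papuan-like focal group, archaic
(Neanderthal/Denisovan-like) reference genomes, introgressed-tract ground
truth, structural variants placed on haplotypes, selective sweeps on existing
alleles, and alpha-satellite higher-order-repeat (HOR) arrays.

Genealogies come from msprime; introgression truth is read off recorded
ancestry (a census at each admixture pulse plus ``link_ancestors``), never
re-inferred. Every entry point takes an explicit seed and is reproducible
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import msprime
import numpy as np
import pandas as pd

from ._util import child_seed, merge_intervals, sha256_of, spawn_rngs

_BASES = np.array(list("ACGT"))

__all__ = [
    "Population",
    "Split",
    "Pulse",
    "DemographicModel",
    "SatelliteSpec",
    "SyntheticCohort",
    "papuan_model",
    "single_pulse_model",
    "expected_tract_length",
    "simulate_cohort",
    "implant_svs",
    "apply_sweep",
    "synthesize_satellite_array",
    "write_cohort",
    "read_cohort",
]


# ---------------------------------------------------------------------------
# demographic model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Population:
    """One population with a diploid effective size, optionally per epoch.

    ``epochs`` lists (time_in_generations, size) changes going into the past;
    ``size`` applies from the present until the first change.
    """

    name: str
    size: float
    epochs: tuple[tuple[float, float], ...] = ()


@dataclass(frozen=True)
class Split:
    """Derived populations merge into ``ancestral`` at ``time`` (generations ago)."""

    time: float
    derived: tuple[str, ...]
    ancestral: str


@dataclass(frozen=True)
class Pulse:
    """Instantaneous admixture: fraction ``fraction`` of ``recipient`` ancestry
    is replaced by ``donor`` lineages at ``time`` generations ago."""

    donor: str
    recipient: str
    time: float
    fraction: float


@dataclass
class DemographicModel:
    populations: list[Population]
    splits: list[Split]
    pulses: list[Pulse]
    recombination_rate: float = 1e-8
    mutation_rate: float = 1.25e-8
    generation_time: float = 29.0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for p in self.populations:
            if p.size <= 0 or any(s <= 0 for _, s in p.epochs):
                raise ValueError(f"population {p.name}: sizes must be > 0")
        for sp in self.splits:
            if sp.time <= 0:
                raise ValueError("split times must be strictly positive")
            for nm in (*sp.derived, sp.ancestral):
                if nm not in names:
                    raise ValueError(f"split references unknown population {nm!r}")
        for pu in self.pulses:
            if not 0 < pu.fraction < 1:
                raise ValueError("pulse fraction must satisfy 0 < m < 1")
            if pu.time <= 0:
                raise ValueError("pulse times must be strictly positive")
            if pu.donor not in names or pu.recipient not in names:
                raise ValueError("pulse references unknown population")
            # the recipient must already exist (forward time) at the pulse:
            # any split creating the recipient must be older than the pulse.
            for sp in self.splits:
                if pu.recipient in sp.derived and sp.time <= pu.time:
                    raise ValueError(
                        f"pulse into {pu.recipient} at t={pu.time} predates the "
                        f"split creating it (t={sp.time})"
                    )
        if self.recombination_rate < 0 or self.mutation_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.generation_time <= 0:
            raise ValueError("generation time must be > 0")

    # -- conversion ---------------------------------------------------------
    def to_demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        for p in self.populations:
            dem.add_population(name=p.name, initial_size=p.size)
            for t, size in p.epochs:
                dem.add_population_parameters_change(
                    time=t, population=p.name, initial_size=size
                )
        for pu in self.pulses:
            # msprime's convention is backwards in time: lineages currently in
            # the recipient move to the donor with probability m.
            dem.add_mass_migration(
                time=pu.time, source=pu.recipient, dest=pu.donor,
                proportion=pu.fraction,
            )
        for sp in self.splits:
            dem.add_population_split(
                time=sp.time, derived=list(sp.derived), ancestral=sp.ancestral
            )
        dem.sort_events()
        return dem

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "populations": [
                {"name": p.name, "size": p.size, "epochs": [list(e) for e in p.epochs]}
                for p in self.populations
            ],
            "splits": [
                {"time": s.time, "derived": list(s.derived), "ancestral": s.ancestral}
                for s in self.splits
            ],
            "pulses": [dataclasses.asdict(p) for p in self.pulses],
            "recombination_rate": self.recombination_rate,
            "mutation_rate": self.mutation_rate,
            "generation_time": self.generation_time,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DemographicModel":
        return cls(
            populations=[
                Population(
                    name=p["name"], size=p["size"],
                    epochs=tuple(tuple(e) for e in p.get("epochs", ())),
                )
                for p in d["populations"]
            ],
            splits=[
                Split(time=s["time"], derived=tuple(s["derived"]), ancestral=s["ancestral"])
                for s in d.get("splits", [])
            ],
            pulses=[Pulse(**p) for p in d.get("pulses", [])],
            recombination_rate=d.get("recombination_rate", 1e-8),
            mutation_rate=d.get("mutation_rate", 1.25e-8),
            generation_time=d.get("generation_time", 29.0),
        )

    @classmethod
    def from_yaml(cls, path) -> "DemographicModel":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def papuan_model(
    ndl_fraction: float = 0.02,
    dns_fraction: float = 0.04,
    ndl_pulse_time: float = 2000.0,
    dns_pulse_time: float = 1500.0,
) -> DemographicModel:
    """Default Papuan-like demography.

    Sizes and split times are round numbers on the scale population-genetic
    models of Oceanian history use (out-of-Africa ~100 kya, archaic divergence
    ~580 kya at 29 y/generation); they are placeholders meant to be edited,
    not estimates. The Neanderthal pulse enters the common ancestor of the
    sister and focal groups; the Denisovan pulse enters the focal group only.
    """
    return DemographicModel(
        populations=[
            Population("AFR", 14000),
            Population("EAS", 5000),
            Population("PNG", 4000),
            Population("OOA", 3000),
            Population("NDL", 3000),
            Population("DNS", 3000),
            Population("ARC", 5000),
            Population("HUM", 10000),
            Population("ROOT", 10000),
        ],
        splits=[
            Split(1800, ("EAS", "PNG"), "OOA"),
            Split(3500, ("AFR", "OOA"), "HUM"),
            Split(15000, ("NDL", "DNS"), "ARC"),
            Split(20000, ("HUM", "ARC"), "ROOT"),
        ],
        pulses=[
            Pulse("NDL", "OOA", ndl_pulse_time, ndl_fraction),
            Pulse("DNS", "PNG", dns_pulse_time, dns_fraction),
        ],
    )


def single_pulse_model(
    m: float = 0.04,
    t: float = 2000.0,
    donor: str = "NDL",
    recombination_rate: float = 1e-8,
    mutation_rate: float = 1.25e-8,
) -> DemographicModel:
    """Three modern populations plus one archaic donor and a single pulse
    of strength ``m`` into the focal population at ``t`` generations ago."""
    if m <= 0:
        # no-admixture control model
        pulses: list[Pulse] = []
    else:
        pulses = [Pulse(donor, "PNG", t, m)]
    return DemographicModel(
        populations=[
            Population("AFR", 14000),
            Population("EAS", 5000),
            Population("PNG", 4000),
            Population("OOA", 3000),
            Population(donor, 3000),
            Population("HUM", 10000),
            Population("ROOT", 10000),
        ],
        splits=[
            Split(max(2400.0, t + 400.0), ("EAS", "PNG"), "OOA"),
            Split(max(3500.0, t + 1500.0), ("AFR", "OOA"), "HUM"),
            Split(20000, ("HUM", donor), "ROOT"),
        ],
        pulses=pulses,
        recombination_rate=recombination_rate,
        mutation_rate=mutation_rate,
    )


# ---------------------------------------------------------------------------
# tract-length expectation
# ---------------------------------------------------------------------------


def expected_tract_length(r: float, t: float) -> float:
    """Mean admixture-tract length, 1/(r*t), for a pulse ``t`` generations ago
    under per-bp per-generation recombination rate ``r``."""
    if r <= 0 or t <= 0:
        raise ValueError("r and t must both be > 0")
    return 1.0 / (r * t)


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort with ground truth.

    ``variants`` holds one row per biallelic SNV (chrom, pos [0-based], ref,
    alt, type); ``genotypes`` is the matching (sites x haplotypes) 0/1 matrix
    with columns ordered as ``haplotypes``. ``truth_tracts`` / ``truth_svs``
    are the ground-truth tables downstream modules are benchmarked against.
    ``sequences`` maps (sample, hap_index) to the haplotype sequence and is
    only populated when requested (it scales with chromosome length).
    """

    chrom: str
    chrom_length: int
    samples: list[str]
    sample_population: dict[str, str]
    haplotypes: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray
    truth_tracts: pd.DataFrame
    truth_svs: pd.DataFrame
    seed: int
    sequences: dict[tuple[str, int], str] | None = None
    n_multiallelic_dropped: int = 0

    def haplotypes_of(self, population: str) -> list[str]:
        return [
            h for h in self.haplotypes
            if self.sample_population[h.rsplit("_hap", 1)[0]] == population
        ]

    def hap_index(self, hap: str) -> int:
        return self.haplotypes.index(hap)

    def derived_positions(self, hap: str) -> np.ndarray:
        """Positions (0-based) where this haplotype carries the derived allele."""
        col = self.genotypes[:, self.hap_index(hap)]
        return self.variants["pos"].to_numpy()[col == 1]

    def tracts_of(self, hap: str) -> pd.DataFrame:
        return self.truth_tracts[self.truth_tracts["haplotype"] == hap]

    def introgressed_fraction(self, population: str) -> float:
        haps = self.haplotypes_of(population)
        if not haps:
            return 0.0
        tr = self.truth_tracts[self.truth_tracts["haplotype"].isin(haps)]
        tot = (tr["end"] - tr["start"]).sum()
        return float(tot) / (len(haps) * self.chrom_length)

    def digest(self) -> str:
        """SHA-256 over all cohort content; identical seeds give identical digests."""
        seq_part = (
            tuple(sorted((f"{s}:{k}", v) for (s, k), v in self.sequences.items()))
            if self.sequences is not None
            else ()
        )
        return sha256_of(
            self.chrom,
            self.chrom_length,
            tuple(self.haplotypes),
            self.variants.to_csv(index=False),
            self.genotypes.astype(np.int8),
            self.truth_tracts.to_csv(index=False),
            self.truth_svs.to_csv(index=False),
            seq_part,
            self.seed,
        )


_EMPTY_TRACTS = {"chrom": [], "start": [], "end": [], "donor": [], "haplotype": []}
_EMPTY_SVS = {
    "chrom": [], "start": [], "end": [], "type": [], "length": [],
    "insert_seq": [], "carriers": [], "on_tract": [], "donor": [],
}


def _empty_tracts() -> pd.DataFrame:
    return pd.DataFrame(_EMPTY_TRACTS).astype(
        {"start": int, "end": int, "chrom": str, "donor": str, "haplotype": str}
    )


def _empty_svs() -> pd.DataFrame:
    return pd.DataFrame(_EMPTY_SVS).astype(
        {"start": int, "end": int, "length": int}
    )


# ---------------------------------------------------------------------------
# coalescent simulation with recorded introgression truth
# ---------------------------------------------------------------------------

_CENSUS_EPS = 0.01


def simulate_cohort(
    model: DemographicModel,
    chrom_length: int,
    n_per_pop: Mapping[str, int],
    seed: int,
    *,
    chrom: str = "chr1",
    archaic_sample_time: float | None = None,
    with_sequences: bool = False,
    tag_density: float = 1e-3,
) -> SyntheticCohort:
    """Simulate a cohort under ``model`` and record introgression ground truth.

    ``n_per_pop`` gives *haplotype* counts per sampled population (must be
    even: samples are diploid). Donor populations named in pulses may also be
    sampled; by default their sampling time is just older than the oldest
    pulse, mimicking ancient archaic reference genomes.

    Truth tracts come from a census placed immediately above each pulse:
    a focal segment is introgressed from donor D iff its lineage sits in D at
    that census. Donor-private variation has two sources: mutations on the
    long archaic branch (density ~2*mu*t_divergence per bp, arising naturally
    from the genealogy) and explicit donor-private "tag" alleles implanted at
    ``tag_density`` per bp on each census ancestor's segments — emulating
    variants fixed on the donor lineage before the pulse. Tags are shared by
    descent among haplotypes inheriting the same ancestral segment and are
    carried by all sampled haplotypes of the donor population.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if chrom_length < 1e5:
        raise ValueError("chrom_length must be >= 1e5")
    model.validate()
    for pop, n in n_per_pop.items():
        if n < 2:
            raise ValueError(f"need >= 2 haplotypes for population {pop}")
        if n % 2:
            raise ValueError(f"haplotype count for {pop} must be even (diploids)")

    donor_names = sorted({p.donor for p in model.pulses})
    pulse_times = sorted({p.time for p in model.pulses})
    if archaic_sample_time is None:
        archaic_sample_time = (max(pulse_times) + 200.0) if pulse_times else 0.0

    dem = model.to_demography()
    for t in pulse_times:
        dem.add_census(time=t + _CENSUS_EPS)
    dem.sort_events()

    sample_sets = []
    pop_order = [p.name for p in model.populations if p.name in n_per_pop]
    for pop in pop_order:
        t_samp = archaic_sample_time if pop in donor_names else 0.0
        sample_sets.append(
            msprime.SampleSet(n_per_pop[pop] // 2, population=pop, time=t_samp)
        )

    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        sequence_length=chrom_length,
        recombination_rate=model.recombination_rate,
        random_seed=child_seed(seed, 0),
    )
    ts = msprime.sim_mutations(
        ts, rate=model.mutation_rate, model="jc69", random_seed=child_seed(seed, 1)
    )

    # --- name haplotypes in sample-set order
    samples: list[str] = []
    haplotypes: list[str] = []
    sample_population: dict[str, str] = {}
    counters = {pop: 0 for pop in pop_order}
    sample_nodes = ts.samples()
    node_to_hap: dict[int, str] = {}
    node_cursor = 0
    for pop in pop_order:
        for _ in range(n_per_pop[pop] // 2):
            counters[pop] += 1
            name = f"{pop}{counters[pop]}"
            samples.append(name)
            sample_population[name] = pop
            for k in (1, 2):
                hap = f"{name}_hap{k}"
                haplotypes.append(hap)
                node_to_hap[int(sample_nodes[node_cursor])] = hap
                node_cursor += 1

    # --- truth tracts from censuses
    tract_rows: list[tuple] = []
    donor_edges: list[tuple] = []  # (donor, left, right, parent_node, haplotype)
    tables = ts.tables
    pop_id = {ts.population(i).metadata.get("name", str(i)): i for i in range(ts.num_populations)}
    node_time = tables.nodes.time
    node_pop = tables.nodes.population
    all_sample_nodes = list(node_to_hap)
    for pu in model.pulses:
        ct = pu.time + _CENSUS_EPS
        census_nodes = np.where(node_time == ct)[0].astype(np.int32)
        if census_nodes.size == 0:
            continue
        # recipient-side sampled haplotypes: anything sampled more recently
        # than the pulse can carry this ancestry.
        recipients = np.array(
            [n for n in all_sample_nodes if node_time[n] < pu.time], dtype=np.int32
        )
        edges = tables.link_ancestors(samples=recipients, ancestors=census_nodes)
        donor_id = pop_id[pu.donor]
        for left, right, parent, child in zip(
            edges.left, edges.right, edges.parent, edges.child
        ):
            if node_pop[parent] == donor_id and int(child) in node_to_hap:
                hap = node_to_hap[int(child)]
                tract_rows.append((chrom, int(left), int(right), pu.donor, hap))
                donor_edges.append((pu.donor, int(left), int(right), int(parent), hap))

    if tract_rows:
        raw = pd.DataFrame(tract_rows, columns=["chrom", "start", "end", "donor", "haplotype"])
        merged_rows = []
        for (hap, donor), grp in raw.groupby(["haplotype", "donor"], sort=True):
            for s, e in merge_intervals(zip(grp["start"], grp["end"])):
                merged_rows.append((chrom, s, e, donor, hap))
        truth_tracts = pd.DataFrame(
            merged_rows, columns=["chrom", "start", "end", "donor", "haplotype"]
        ).sort_values(["haplotype", "start"], kind="mergesort").reset_index(drop=True)
    else:
        truth_tracts = _empty_tracts()

    # --- biallelic variant table
    positions, refs, alts, geno_rows = [], [], [], []
    n_multi = 0
    for var in ts.variants():
        if len(var.alleles) != 2:
            n_multi += 1
            continue
        positions.append(int(var.site.position))
        refs.append(var.alleles[0])
        alts.append(var.alleles[1])
        geno_rows.append(var.genotypes.astype(np.int8))
    # --- implant donor-private tag alleles on census ancestors
    if tag_density > 0 and donor_edges:
        rng_tag = spawn_rngs(seed, ["tags"])["tags"]
        hap_col = {h: j for j, h in enumerate(haplotypes)}
        existing = set(positions)
        by_parent: dict[tuple[str, int], list[tuple[int, int, str]]] = {}
        for donor, left, right, parent, hap in donor_edges:
            by_parent.setdefault((donor, parent), []).append((left, right, hap))
        donor_cols = {
            d: [hap_col[h] for h in haplotypes
                if sample_population[h.rsplit("_hap", 1)[0]] == d]
            for d in {de[0] for de in donor_edges}
        }
        for (donor, parent), segs in sorted(by_parent.items()):
            for s, e in merge_intervals([(l, r) for l, r, _ in segs]):
                n_tags = rng_tag.poisson(tag_density * (e - s))
                if n_tags == 0:
                    continue
                for p in np.unique(rng_tag.integers(s, e, size=n_tags)):
                    p = int(p)
                    if p in existing:
                        continue
                    existing.add(p)
                    ref = str(rng_tag.choice(_BASES))
                    alt = str(rng_tag.choice([b for b in "ACGT" if b != ref]))
                    row = np.zeros(len(haplotypes), dtype=np.int8)
                    for l, r, hap in segs:
                        if l <= p < r:
                            row[hap_col[hap]] = 1
                    row[donor_cols[donor]] = 1  # fixed in the donor population
                    positions.append(p)
                    refs.append(ref)
                    alts.append(alt)
                    geno_rows.append(row)

    genotypes = (
        np.vstack(geno_rows) if geno_rows else np.zeros((0, len(haplotypes)), np.int8)
    )
    pos_arr = np.asarray(positions, dtype=int)
    order = np.argsort(pos_arr, kind="stable")
    genotypes = genotypes[order]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos_arr[order],
            "ref": np.asarray(refs, dtype=object)[order],
            "alt": np.asarray(alts, dtype=object)[order],
            "type": "SNV",
        }
    )

    sequences = None
    if with_sequences:
        rng = spawn_rngs(seed, ["refseq"])["refseq"]
        ref_arr = rng.choice(_BASES, size=chrom_length)
        pos_arr = variants["pos"].to_numpy()
        ref_arr[pos_arr] = variants["ref"].to_numpy()
        sequences = {}
        for j, hap in enumerate(haplotypes):
            arr = ref_arr.copy()
            der = genotypes[:, j] == 1
            arr[pos_arr[der]] = variants["alt"].to_numpy()[der]
            sample, k = hap.rsplit("_hap", 1)
            sequences[(sample, int(k))] = "".join(arr)

    return SyntheticCohort(
        chrom=chrom,
        chrom_length=int(chrom_length),
        samples=samples,
        sample_population=sample_population,
        haplotypes=haplotypes,
        variants=variants,
        genotypes=genotypes,
        truth_tracts=truth_tracts,
        truth_svs=_empty_svs(),
        seed=int(seed),
        sequences=sequences,
        n_multiallelic_dropped=n_multi,
    )


# ---------------------------------------------------------------------------
# structural variants
# ---------------------------------------------------------------------------


def implant_svs(
    cohort: SyntheticCohort,
    sv_density: float | None = None,
    length_distribution: Callable[[np.random.Generator], int] | None = None,
    seed: int | None = None,
    *,
    n_svs: int | None = None,
    type_probs: Sequence[float] = (0.5, 0.45, 0.05),  # INS, DEL, INV
    inside_tracts_only: bool = False,
    max_carriers: int = 4,
) -> SyntheticCohort:
    """Return a copy of ``cohort`` with typed SVs placed on haplotypes.

    The number of SVs is Poisson(sv_density * chrom_length) unless ``n_svs``
    fixes it. DEL/INV intervals are half-open on the reference; INS records a
    1 bp breakpoint interval and carries its inserted sequence. With
    ``inside_tracts_only`` every SV is placed fully within a truth tract of
    its (single) carrier haplotype. SVs that would run past the chromosome
    end are rejected and resampled.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if sv_density is None and n_svs is None:
        raise ValueError("give sv_density or n_svs")
    if sv_density is not None and sv_density < 0:
        raise ValueError("sv_density must be >= 0")
    rng = spawn_rngs(seed, ["svs"])["svs"]
    if length_distribution is None:
        length_distribution = lambda r: int(r.integers(50, 1000))  # noqa: E731
    if n_svs is None:
        n_svs = int(rng.poisson(sv_density * cohort.chrom_length))

    tract_df = cohort.truth_tracts
    types = np.array(["INS", "DEL", "INV"])
    probs = np.asarray(type_probs, dtype=float)
    probs = probs / probs.sum()

    def _lookup_tract(hap: str, start: int, end: int) -> tuple[bool, str]:
        tr = tract_df[tract_df["haplotype"] == hap]
        hit = tr[(tr["start"] <= start) & (tr["end"] >= end)]
        if len(hit):
            return True, str(hit.iloc[0]["donor"])
        return False, ""

    rows = []
    for _ in range(n_svs):
        svtype = str(rng.choice(types, p=probs))
        length = max(50, int(length_distribution(rng)))
        span = 1 if svtype == "INS" else length
        if inside_tracts_only:
            if tract_df.empty:
                raise ValueError("inside_tracts_only requested but cohort has no tracts")
            lens = (tract_df["end"] - tract_df["start"]).to_numpy()
            ok = np.where(lens >= span)[0]
            if ok.size == 0:
                raise ValueError("no truth tract long enough for requested SV length")
            row = tract_df.iloc[int(rng.choice(ok, p=lens[ok] / lens[ok].sum()))]
            start = int(rng.integers(row["start"], row["end"] - span + 1))
            carriers = (str(row["haplotype"]),)
            on_tract, donor = True, str(row["donor"])
        else:
            # uniform placement; resample on chromosome-end overflow
            while True:
                start = int(rng.integers(0, cohort.chrom_length))
                if start + span <= cohort.chrom_length:
                    break
            k = min(1 + int(rng.geometric(0.6)) - 1, max_carriers, len(cohort.haplotypes))
            k = max(k, 1)
            carriers = tuple(
                sorted(rng.choice(cohort.haplotypes, size=k, replace=False))
            )
            on_tract, donor = False, ""
            for hap in carriers:
                hit, d = _lookup_tract(hap, start, start + span)
                if hit:
                    on_tract, donor = True, d
                    break
        insert_seq = (
            "".join(rng.choice(_BASES, size=length)) if svtype == "INS" else ""
        )
        rows.append(
            (
                cohort.chrom, start, start + span, svtype, length,
                insert_seq, ",".join(carriers), on_tract, donor,
            )
        )

    svs = pd.DataFrame(rows, columns=list(_EMPTY_SVS)) if rows else _empty_svs()
    if len(svs):
        svs = svs.sort_values(["start", "end", "type"], kind="mergesort").reset_index(drop=True)
    out = dataclasses.replace(cohort)
    out.truth_svs = svs
    return out


# ---------------------------------------------------------------------------
# sweeps (forward layer)
# ---------------------------------------------------------------------------


def apply_sweep(
    cohort: SyntheticCohort,
    position: int,
    s: float,
    generations: int,
    seed: int,
    population: str = "PNG",
) -> SyntheticCohort:
    """Emulate positive selection on an existing allele by haplotype resampling.

    The derived-allele frequency at ``position`` is advanced
    deterministically for ``generations`` rounds of genic selection
    (p' = p + s*p*(1-p)/(1+s*p)); the focal population's haplotype pool is
    then resampled with replacement so carriers reach the new frequency.
    Linked variation is dragged along (no recombination within the region,
    as for a short, tightly linked window) and coalescence among carriers is
    compressed; drift during the sweep is not modelled — the sample is a
    window on a much larger population.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    pos_arr = cohort.variants["pos"].to_numpy()
    site_idx = np.where(pos_arr == position)[0]
    if site_idx.size == 0:
        raise ValueError(f"no variant at position {position}")
    site = int(site_idx[0])
    focal = np.array(
        [j for j, h in enumerate(cohort.haplotypes)
         if cohort.sample_population[h.rsplit("_hap", 1)[0]] == population]
    )
    rng = spawn_rngs(seed, ["sweep"])["sweep"]
    geno = cohort.genotypes.copy()
    carriers = focal[geno[site, focal] == 1]
    others = focal[geno[site, focal] == 0]
    if carriers.size == 0:
        raise ValueError("selected allele absent from the focal population")
    p = carriers.size / focal.size
    for _ in range(generations):
        p = p + s * p * (1 - p) / (1 + s * p)
    n_carrier = int(np.clip(rng.binomial(focal.size, p), 1, focal.size))
    picks = np.concatenate(
        [
            rng.choice(carriers, size=n_carrier, replace=True),
            rng.choice(others, size=focal.size - n_carrier, replace=True)
            if focal.size > n_carrier
            else np.empty(0, dtype=int),
        ]
    ).astype(int)
    idx = picks
    geno[:, focal] = geno[:, idx]
    out = dataclasses.replace(cohort)
    out.genotypes = geno
    if cohort.sequences is not None:
        seqs = dict(cohort.sequences)
        names = [cohort.haplotypes[j] for j in focal]
        donors = [cohort.haplotypes[j] for j in idx]
        for name, donor in zip(names, donors):
            srec, k = name.rsplit("_hap", 1)
            sdon, kd = donor.rsplit("_hap", 1)
            seqs[(srec, int(k))] = cohort.sequences[(sdon, int(kd))]
        out.sequences = seqs
    return out


# ---------------------------------------------------------------------------
# alpha-satellite HOR arrays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SatelliteSpec:
    """Parameters of a synthetic alpha-satellite higher-order-repeat array.

    ``substitution_rate`` is the per-base probability that a HOR copy differs
    from the ancestral unit; ``flank_length`` bases of unique sequence are
    added on *each* side of the array.
    """

    monomer_length: int = 171
    monomers_per_hor: int = 12
    hor_copies: int = 10
    substitution_rate: float = 0.0
    flank_length: int = 0

    def __post_init__(self) -> None:
        if min(self.monomer_length, self.monomers_per_hor, self.hor_copies) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution rate must be in [0, 1)")
        if self.flank_length < 0:
            raise ValueError("flank length must be >= 0")


def synthesize_satellite_array(
    spec: SatelliteSpec, seed: int
) -> tuple[str, pd.DataFrame]:
    """Build a HOR array: an ancestral unit of random monomers, tandem copies
    each independently mutated at the spec's substitution rate, plus unique
    flanks. Returns (sequence, annotation) where the annotation intervals
    (0-based half-open) tile the array exactly, one row per HOR copy."""
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    rng = spawn_rngs(seed, ["satellite"])["satellite"]
    unit_len = spec.monomer_length * spec.monomers_per_hor
    unit = rng.choice(_BASES, size=unit_len)
    copies = []
    for _ in range(spec.hor_copies):
        cp = unit.copy()
        if spec.substitution_rate > 0:
            hit = rng.random(unit_len) < spec.substitution_rate
            n_hit = int(hit.sum())
            if n_hit:
                shift = rng.integers(1, 4, size=n_hit)
                codes = np.searchsorted(_BASES, cp[hit])
                cp[hit] = _BASES[(codes + shift) % 4]
        copies.append(cp)
    left = rng.choice(_BASES, size=spec.flank_length)
    right = rng.choice(_BASES, size=spec.flank_length)
    seq = "".join(np.concatenate([left, *copies, right]))
    starts = spec.flank_length + unit_len * np.arange(spec.hor_copies)
    annot = pd.DataFrame(
        {"start": starts, "end": starts + unit_len, "copy": np.arange(spec.hor_copies)}
    )
    return seq, annot


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------

_FASTA_WIDTH = 80


def _write_fasta(path: Path, records: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write the cohort in standard formats under ``out_dir``.

    Files: ``cohort.vcf`` (multi-sample SNVs, phased GT), ``svs.vcf``
    (symbolic SV alleles with SVTYPE/SVLEN/END and INSSEQ for insertions),
    ``truth_tracts.bed`` and ``truth_svs.bed`` (0-based half-open; column 4
    carries the donor label / the SV type as INS:len, DEL, INV),
    ``haplotypes.fasta`` when sequences are present, and ``meta.json``.
    Output is deterministic: write -> read -> write is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    header = [
        "##fileformat=VCFv4.2",
        "##source=introscan-simgen",
        f"##contig=<ID={cohort.chrom},length={cohort.chrom_length}>",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of SV (1-based inclusive)">',
        '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Inserted sequence">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.samples),
    ]

    snv_path = out / "cohort.vcf"
    with open(snv_path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        pos = cohort.variants["pos"].to_numpy()
        refs = cohort.variants["ref"].to_numpy()
        alts = cohort.variants["alt"].to_numpy()
        for i in range(len(cohort.variants)):
            gts = "\t".join(
                f"{cohort.genotypes[i, 2 * j]}|{cohort.genotypes[i, 2 * j + 1]}"
                for j in range(len(cohort.samples))
            )
            fh.write(
                f"{cohort.chrom}\t{pos[i] + 1}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    paths["snv_vcf"] = snv_path

    sv_path = out / "svs.vcf"
    with open(sv_path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for _, row in cohort.truth_svs.iterrows():
            carriers = set(str(row["carriers"]).split(",")) if row["carriers"] else set()
            gts = []
            for sample in cohort.samples:
                a = int(f"{sample}_hap1" in carriers)
                b = int(f"{sample}_hap2" in carriers)
                gts.append(f"{a}|{b}")
            info = f"SVTYPE={row['type']};SVLEN={row['length']};END={row['end']}"
            if row["type"] == "INS" and row["insert_seq"]:
                info += f";INSSEQ={row['insert_seq']}"
            fh.write(
                f"{cohort.chrom}\t{row['start'] + 1}\t.\tN\t<{row['type']}>\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts) + "\n"
            )
    paths["sv_vcf"] = sv_path

    tr_path = out / "truth_tracts.bed"
    with open(tr_path, "w") as fh:
        for _, row in cohort.truth_tracts.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{row['donor']}\t{row['haplotype']}\n"
            )
    paths["tract_bed"] = tr_path

    svb_path = out / "truth_svs.bed"
    with open(svb_path, "w") as fh:
        for _, row in cohort.truth_svs.iterrows():
            label = f"INS:{row['length']}" if row["type"] == "INS" else row["type"]
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{label}\t"
                f"{row['carriers']}\t{int(row['on_tract'])}\t{row['donor']}\t"
                f"{row['insert_seq']}\n"
            )
    paths["sv_bed"] = svb_path

    if cohort.sequences is not None:
        fa_path = out / "haplotypes.fasta"
        recs = [
            (f"{s}_hap{k}", cohort.sequences[(s, k)])
            for s in cohort.samples
            for k in (1, 2)
            if (s, k) in cohort.sequences
        ]
        _write_fasta(fa_path, recs)
        paths["fasta"] = fa_path

    meta = {
        "chrom": cohort.chrom,
        "chrom_length": cohort.chrom_length,
        "samples": cohort.samples,
        "sample_population": cohort.sample_population,
        "haplotypes": cohort.haplotypes,
        "seed": cohort.seed,
        "n_multiallelic_dropped": cohort.n_multiallelic_dropped,
        "has_sequences": cohort.sequences is not None,
    }
    meta_path = out / "meta.json"
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    paths["meta"] = meta_path
    return paths


def read_cohort(in_dir) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    from cyvcf2 import VCF

    ind = Path(in_dir)
    meta = json.loads((ind / "meta.json").read_text())
    samples = meta["samples"]
    haplotypes = meta["haplotypes"]

    rows, geno_rows = [], []
    vcf = VCF(str(ind / "cohort.vcf"))
    for var in vcf:
        rows.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0], "SNV"))
        g = np.array([(gt[0], gt[1]) for gt in var.genotypes], dtype=np.int8).ravel()
        geno_rows.append(g)
    vcf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "type"])
    genotypes = (
        np.vstack(geno_rows) if geno_rows else np.zeros((0, len(haplotypes)), np.int8)
    )

    sv_rows = []
    svvcf = VCF(str(ind / "svs.vcf"))
    for var in svvcf:
        svtype = var.INFO.get("SVTYPE")
        length = int(var.INFO.get("SVLEN"))
        end = int(var.INFO.get("END"))
        insseq = var.INFO.get("INSSEQ") or ""
        carriers = []
        for j, gt in enumerate(var.genotypes):
            if gt[0]:
                carriers.append(f"{samples[j]}_hap1")
            if gt[1]:
                carriers.append(f"{samples[j]}_hap2")
        sv_rows.append(
            (var.CHROM, var.POS - 1, end, svtype, length, insseq,
             ",".join(sorted(carriers)), False, "")
        )
    svvcf.close()

    tr_path = ind / "truth_tracts.bed"
    if tr_path.stat().st_size:
        truth_tracts = pd.read_csv(
            tr_path, sep="\t", header=None,
            names=["chrom", "start", "end", "donor", "haplotype"],
        )
    else:
        truth_tracts = _empty_tracts()

    svb = ind / "truth_svs.bed"
    if svb.stat().st_size:
        bed = pd.read_csv(
            svb, sep="\t", header=None,
            names=["chrom", "start", "end", "label", "carriers", "on_tract",
                   "donor", "insert_seq"],
            keep_default_na=False,
        )
        truth_svs = pd.DataFrame(
            {
                "chrom": bed["chrom"],
                "start": bed["start"].astype(int),
                "end": bed["end"].astype(int),
                "type": [str(l).split(":")[0] for l in bed["label"]],
                "length": [
                    int(str(l).split(":")[1]) if ":" in str(l) else int(e) - int(s)
                    for l, s, e in zip(bed["label"], bed["start"], bed["end"])
                ],
                "insert_seq": bed["insert_seq"].astype(str),
                "carriers": bed["carriers"].astype(str),
                "on_tract": bed["on_tract"].astype(bool),
                "donor": bed["donor"].astype(str),
            }
        )
    else:
        truth_svs = _empty_svs()

    sequences = None
    if meta.get("has_sequences"):
        from pyfaidx import Fasta

        fa = Fasta(str(ind / "haplotypes.fasta"))
        sequences = {}
        for name in fa.keys():
            sample, k = name.rsplit("_hap", 1)
            sequences[(sample, int(k))] = str(fa[name][:])
        fa.close()
        for suffix in (".fai",):
            p = ind / ("haplotypes.fasta" + suffix)
            if p.exists():
                p.unlink()

    return SyntheticCohort(
        chrom=meta["chrom"],
        chrom_length=meta["chrom_length"],
        samples=samples,
        sample_population=meta["sample_population"],
        haplotypes=haplotypes,
        variants=variants,
        genotypes=genotypes,
        truth_tracts=truth_tracts,
        truth_svs=truth_svs,
        seed=meta["seed"],
        sequences=sequences,
        n_multiallelic_dropped=meta.get("n_multiallelic_dropped", 0),
    )
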