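"""Synthetic data with known planted truth for every pipeline stage.

Three generators:

* :func:`simulate_pileup` emulates per-site pileup summaries from ~63x
  shotgun resequencing of a bacterial genome: planted variants draw
  supporting-read counts from Binomial(depth, true_frequency) and split
  them across strands by Binomial(alt_depth, strand_skew); spurious
  low-frequency noise variants exercise the filter's rejection path.
* :func:`simulate_proteome` builds proteomes in which a few planted
  RTX-like cargo proteins (large, acidic, cysteine-poor, Ca-repeat
  signature, C-terminal GGXGXDXXX nonamers) hide among decoys that are
  guaranteed not to satisfy the full cargo criteria.
* :func:`simulate_reactor` is the deterministic forward model inverse
  to the founder back-calculation: biofilm cells double every
  generation time until the areal protein reaches the reactor carrying
  capacity, and observations below the detection limit are emitted as
  censored, never as quantified values.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cargo import (
    CargoCriteria,
    ProteinRecord,
    pi_from_counts,
    PKA_SETS,
    screen_protein,
)
from .errors import DataError
from .prosite import load_ps00330, parse_prosite_pattern, scan_pattern
from collections import Counter

__all__ = [
    "PlantedVariant",
    "PileupPlan",
    "PlantedCargo",
    "ReactorParams",
    "simulate_pileup",
    "simulate_proteome",
    "simulate_reactor",
    "MO_UNIQUE_VARIANTS",
    "strain_divergence_plan",
]

PILEUP_COLUMNS = ["sample", "pos", "ref", "alt", "depth", "alt_depth", "alt_fwd", "alt_rev"]


@dataclass(frozen=True)
class PlantedVariant:
    position: int
    ref_allele: str
    alt_allele: str
    true_frequency: float
    strand_skew: float = 0.5
    samples: frozenset = frozenset()

    def __post_init__(self):
        if self.ref_allele.upper() == self.alt_allele.upper():
            raise DataError(f"planted variant at {self.position}: ref == alt")
        if not (0 <= self.true_frequency <= 1 and 0 <= self.strand_skew <= 1):
            raise DataError("true_frequency and strand_skew must be in [0, 1]")
        object.__setattr__(self, "samples", frozenset(self.samples))

    @property
    def span(self) -> tuple[int, int]:
        return (self.position, self.position + len(self.ref_allele) - 1)


@dataclass(frozen=True)
class PileupPlan:
    samples: tuple[str, ...]
    variants: tuple[PlantedVariant, ...] = ()
    mean_depth: float = 63.0  # average resequencing coverage
    depth_model: str = "poisson"  # "poisson" | "fixed"
    noise_rate: float = 0.0  # per-site probability of a spurious variant
    genome_length: int = 3_570_000
    seed: int = 0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise DataError("mean_depth must be positive")
        if not 0 <= self.noise_rate < 1:
            raise DataError("noise_rate must be in [0, 1)")
        if self.depth_model not in ("poisson", "fixed"):
            raise DataError(f"unknown depth model {self.depth_model!r}")
        if len(set(self.samples)) != len(self.samples) or not self.samples:
            raise DataError("samples must be non-empty and unique")
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "variants", tuple(self.variants))


def _check_no_overlap(plan: PileupPlan) -> None:
    for sample in plan.samples:
        spans = sorted(v.span for v in plan.variants if sample in v.samples)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise DataError(
                    f"overlapping planted variants in sample {sample!r}: "
                    f"spans {(s1, e1)} and {(s2, e2)}"
                )


def _draw_depth(rng: np.random.Generator, plan: PileupPlan) -> int:
    if plan.depth_model == "fixed":
        return int(round(plan.mean_depth))
    return int(rng.poisson(plan.mean_depth))


_BASES = "ACGT"

# Spurious variants are planted below the 10% acceptance rule
# (Uniform(0.01, 0.08) true frequency) with artifact-like strand skew
# drawn Uniform(0, 1), mimicking mapping/sequencing artifacts.
NOISE_FREQ_RANGE = (0.01, 0.08)


def simulate_pileup(plan: PileupPlan) -> pd.DataFrame:
    """Pileup summary table (one row per candidate site per sample).

    Every planted-variant site is reported for every sample (carriers
    with sampled supporting reads, non-carriers with zero), so the
    cross-sample classifier sees the full frequency matrix; noise sites
    appear only in the affected sample.
    """
    _check_no_overlap(plan)
    rng = np.random.default_rng(plan.seed)
    rows: list[tuple] = []
    planted_positions = set()
    for v in plan.variants:
        planted_positions.update(range(v.span[0], v.span[1] + 1))
    for v in sorted(plan.variants, key=lambda v: v.position):
        for sample in plan.samples:
            depth = _draw_depth(rng, plan)
            if sample in v.samples and depth > 0:
                alt = int(rng.binomial(depth, v.true_frequency))
                fwd = int(rng.binomial(alt, v.strand_skew)) if alt else 0
            else:
                alt = fwd = 0
            rows.append(
                (sample, v.position, v.ref_allele, v.alt_allele, depth, alt, fwd, alt - fwd)
            )
    if plan.noise_rate > 0:
        lo, hi = NOISE_FREQ_RANGE
        for sample in plan.samples:
            n_noise = int(rng.binomial(plan.genome_length, plan.noise_rate))
            placed = 0
            while placed < n_noise:
                pos = int(rng.integers(1, plan.genome_length + 1))
                if pos in planted_positions:
                    continue
                depth = _draw_depth(rng, plan)
                freq = float(rng.uniform(lo, hi))
                skew = float(rng.uniform())
                ref, alt_base = rng.choice(4, size=2, replace=False)
                alt = int(rng.binomial(depth, freq)) if depth else 0
                fwd = int(rng.binomial(alt, skew)) if alt else 0
                rows.append(
                    (sample, pos, _BASES[ref], _BASES[alt_base], depth, alt, fwd, alt - fwd)
                )
                placed += 1
    df = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    return df.sort_values(["pos", "sample"], kind="stable").reset_index(drop=True)


def planted_truth_table(plan: PileupPlan) -> pd.DataFrame:
    """Sidecar describing the planted truth (for writing next to the pileup)."""
    rows = [
        (v.position, v.ref_allele, v.alt_allele, v.true_frequency, v.strand_skew,
         ",".join(sorted(v.samples)))
        for v in sorted(plan.variants, key=lambda v: v.position)
    ]
    return pd.DataFrame(
        rows, columns=["pos", "ref", "alt", "true_frequency", "strand_skew", "samples"]
    )


# ---------------------------------------------------------------------------
# proteome simulation

@dataclass(frozen=True)
class PlantedCargo:
    """Recipe for one synthetic T1SS cargo protein."""

    length: int = 2500
    n_nonamers: int = 4
    nonamer_window: float = 0.25  # fraction of C-terminal sequence receiving repeats
    target_pI_band: tuple[float, float] = (3.8, 4.4)
    n_cys: int = 0
    embed_ps00330: bool = True

    def __post_init__(self):
        if self.length < 200:
            raise DataError("cargo length must be at least 200 aa")
        if not 0 < self.nonamer_window <= 1:
            raise DataError("nonamer_window must be in (0, 1]")
        if self.n_cys < 0 or self.n_nonamers < 0:
            raise DataError("counts must be non-negative")
        span = int(self.nonamer_window * self.length)
        if self.n_nonamers * 14 > span:
            raise DataError("C-terminal window too small for the requested repeats")


# Background residues exclude Asp (the nonamer's only non-Gly anchor) and
# Cys, so accidental GGXGXDXXX matches and stray cysteines cannot arise;
# Glu provides acidity instead of Asp.
_BACKGROUND = "AEFGHIKLMNPQRSTVWY".replace("G", "")  # G added separately at low rate
_NONAMER_X = "ASTNQLIVEHM"  # wildcard slots: no G, D, C
_PS00330_SEGMENT = "DALAAAAGADALAGGAAAD"  # matches the bundled Ca-repeat signature


def _random_background(rng: np.random.Generator, n: int) -> list[str]:
    # ~12% E keeps composition acidic; ~8% G below Gly/Ala-segment threshold
    letters = list(_BACKGROUND)
    probs = np.full(len(letters), (1 - 0.12 - 0.08 - 0.02) / (len(letters) - 3))
    for aa, p in (("E", 0.12), ("K", 0.02)):
        probs[letters.index(aa)] = p
    probs /= probs.sum()
    seq = [letters[i] for i in rng.choice(len(letters), size=n, p=probs)]
    g_sites = rng.choice(n, size=max(1, int(0.08 * n)), replace=False)
    for i in g_sites:
        seq[i] = "G"
    return seq


def _make_nonamer(rng: np.random.Generator) -> str:
    x = lambda: _NONAMER_X[rng.integers(len(_NONAMER_X))]
    return "GG" + x() + "G" + x() + "D" + x() + x() + x()


def _build_cargo(rng: np.random.Generator, recipe: PlantedCargo, nonamer_pat, ca_pat) -> str:
    n = recipe.length
    seq = _random_background(rng, n)
    locked: set[int] = set()

    def place(segment: str, at: int) -> None:
        for j, aa in enumerate(segment):
            seq[at + j] = aa
            locked.add(at + j)

    win_start = n - int(recipe.nonamer_window * n)  # 0-based start of C-terminal window
    # Gly/Ala-rich block in the N-terminal half
    block = ["G" if rng.random() < 0.45 else ("A" if rng.random() < 0.6 else "S") for _ in range(40)]
    place("".join(block), max(0, int(0.1 * n)))
    if recipe.embed_ps00330:
        place(_PS00330_SEGMENT, max(0, win_start - len(_PS00330_SEGMENT) - 5))
    cursor = win_start + 2
    for _ in range(recipe.n_nonamers):
        place(_make_nonamer(rng), cursor)
        cursor += 9 + int(rng.integers(3, 6))  # spacer free of G/D by background redraw
        if cursor + 9 > n:
            raise DataError("C-terminal window too small for the requested repeats")
    # spacers between repeats must not introduce G or D next to repeat starts
    for i in range(win_start, n):
        if i not in locked and seq[i] in "G":
            seq[i] = "S"
    for i in range(recipe.n_cys):
        while True:
            j = int(rng.integers(0, n))
            if j not in locked:
                seq[j] = "C"
                locked.add(j)
                break
    _tune_pi(rng, seq, locked, recipe.target_pI_band)
    s = "".join(seq)
    _verify_cargo(s, recipe, nonamer_pat, ca_pat)
    return s


def _tune_pi(rng, seq: list[str], locked: set[int], band: tuple[float, float]) -> None:
    lo, hi = band
    pka = PKA_SETS["bjellqvist"]
    counts = Counter(seq)
    for _ in range(4000):
        pi = pi_from_counts(counts, pka, seq[0], seq[-1])
        if lo <= pi <= hi:
            return
        if pi > hi:
            src, dst = "QNSTLIVAFM", "E"  # acidify
        else:
            src, dst = "E", "Q"  # neutralise
        candidates = [i for i, aa in enumerate(seq) if aa in src and i not in locked]
        if not candidates:
            break
        j = int(rng.choice(candidates))
        counts[seq[j]] -= 1
        counts[dst] += 1
        seq[j] = dst
    raise DataError(f"infeasible pI band {band} for the requested composition")


def _verify_cargo(s: str, recipe: PlantedCargo, nonamer_pat, ca_pat) -> None:
    hits = scan_pattern(s, nonamer_pat)
    win_start_1 = len(s) - int(recipe.nonamer_window * len(s)) + 1
    inside = [h for h in hits if h.start >= win_start_1]
    if len(inside) != recipe.n_nonamers or len(hits) != len(inside):
        raise DataError(
            f"cargo construction planted {len(inside)}/{len(hits)} nonamers, "
            f"requested {recipe.n_nonamers}"
        )
    if recipe.embed_ps00330 and not scan_pattern(s, ca_pat):
        raise DataError("cargo construction lost the Ca-repeat signature")
    if s.count("C") != recipe.n_cys:
        raise DataError("cargo construction produced a wrong cysteine count")


def _dipeptide_shuffle(rng: np.random.Generator, s: str) -> str:
    """Shuffle the non-overlapping dipeptide tiling (preserves tile composition)."""
    pairs = [s[i : i + 2] for i in range(0, len(s) - 1, 2)]
    tail = s[len(pairs) * 2 :]
    order = rng.permutation(len(pairs))
    return "".join(pairs[i] for i in order) + tail


def simulate_proteome(
    n_decoys: int,
    cargo: Sequence[PlantedCargo],
    seed: int = 0,
    criteria: CargoCriteria | None = None,
    max_attempts: int = 50,
) -> list[ProteinRecord]:
    """Planted cargo followed by decoys, FASTA-writable.

    Decoys alternate between dipeptide-tile shuffles of the planted
    cargo (realistic composition, motifs destroyed) and short
    random-composition proteins; every decoy is screened against
    ``criteria`` and rejected (re-drawn) if it would pass.
    """
    if n_decoys < 0:
        raise DataError("n_decoys must be non-negative")
    rng = np.random.default_rng(seed)
    criteria = criteria or CargoCriteria()
    nonamer_pat = parse_prosite_pattern(criteria.nonamer_pattern)
    ca_pat = load_ps00330()
    records: list[ProteinRecord] = []
    for i, recipe in enumerate(cargo, start=1):
        for attempt in range(max_attempts):
            try:
                s = _build_cargo(rng, recipe, nonamer_pat, ca_pat)
                break
            except DataError as exc:
                if "infeasible pI band" in str(exc) or attempt == max_attempts - 1:
                    raise
        records.append(ProteinRecord(f"cargo_{i}", "planted T1SS cargo", s))
    for i in range(1, n_decoys + 1):
        for _ in range(max_attempts):
            if records and i % 2 == 0:
                src = records[int(rng.integers(0, len(cargo)))] if cargo else None
                s = _dipeptide_shuffle(rng, src.sequence) if src else None
            else:
                s = None
            if s is None:
                length = int(rng.integers(150, 900))
                s = "".join(_random_background(rng, length))
            rec = ProteinRecord(f"decoy_{i:03d}", "decoy", s)
            if screen_protein(rec, criteria, ca_pat, nonamer_pat).verdict == "rejected":
                records.append(rec)
                break
        else:
            raise DataError("could not generate a decoy failing the cargo criteria")
    return records


# ---------------------------------------------------------------------------
# reactor simulation

@dataclass(frozen=True)
class ReactorParams:
    vessel_area: float = 231.0  # cm2
    slide_area: float = 15.0  # cm2 per slide
    n_slides: int = 7
    protein_per_cell: float = 278.0  # fg
    generation_time: float = 6.8  # h
    batch_lead: float = 24.0  # h of batch growth before continuous flow
    detection_limit: float = 1.3  # ug/cm2
    carrying_capacity: float = 400.0  # ug/cm2
    seed: int = 0

    def __post_init__(self):
        for name in ("vessel_area", "slide_area", "protein_per_cell",
                     "generation_time", "batch_lead", "detection_limit",
                     "carrying_capacity"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be strictly positive")
        if self.n_slides < 1:
            raise DataError("n_slides must be strictly positive")
        if self.detection_limit >= self.carrying_capacity:
            raise DataError("detection_limit must be below carrying_capacity")

    @property
    def total_area(self) -> float:
        return self.vessel_area + self.n_slides * self.slide_area


def simulate_reactor(
    params: ReactorParams,
    founders: float,
    duration: float,
    sample_every: float = 24.0,
) -> pd.DataFrame:
    """Deterministic biofilm trajectory (time_h, protein_ug_per_cm2, censored).

    Time is total residence time since inoculation.  Cells double every
    ``generation_time`` (2^(t/g), so the doubling ratio is exact below
    capacity); areal protein saturates at the carrying capacity; values
    below the detection limit are reported *at* the detection limit with
    ``censored=True`` so no sub-detection number is ever quantified.
    """
    if duration <= 0:
        raise DataError("duration must be positive")
    if founders < 0:
        raise DataError("founders must be non-negative")
    if sample_every <= 0:
        raise DataError("sample_every must be positive")
    times = np.arange(0.0, duration + 1e-9, sample_every)
    cells = founders * np.exp2(times / params.generation_time)
    areal = cells * params.protein_per_cell / (params.total_area * 1e9)
    areal = np.minimum(areal, params.carrying_capacity)
    censored = areal < params.detection_limit
    reported = np.where(censored, params.detection_limit, areal)
    return pd.DataFrame(
        {"time_h": times, "protein_ug_per_cm2": reported, "censored": censored}
    )


# ---------------------------------------------------------------------------
# the strain-divergence scenario

# The twelve mutations unique to the MO lineage of D. vulgaris
# Hildenborough (chromosomal coordinates on NC_002937.3 except the last
# two, which sit on plasmid pDV at bp 40,114 and 92,886; site keys here
# are replicon-agnostic).  Includes the DVU1017 G1118956C change behind
# the A635P transporter substitution.
MO_UNIQUE_VARIANTS: tuple[tuple[int, str, str], ...] = (
    (268940, "A", "T"),
    (468337, "C", "G"),
    (1034706, "A", "C"),
    (1118956, "G", "C"),
    (1213311, "G", "A"),
    (1884231, "G", "C"),
    (2099891, "G", "A"),
    (2904348, "T", "G"),
    (2918165, "C", "T"),
    (3098151, "C", "G"),
    (40114, "G", "C"),
    (92886, "A", "T"),
)

SAMPLES = ("MT-batch", "MO-batch", "MO-biofilm")
STRAIN_OF_SAMPLE = {"MT-batch": "MT", "MO-batch": "MO", "MO-biofilm": "MO"}
LATER_SAMPLES = ("MO-biofilm",)


def strain_divergence_plan(
    seed: int = 0,
    n_shared: int = 29,
    noise_rate: float = 2e-6,
    unique_frequency: float = 0.98,
    shared_frequency: float = 0.99,
) -> PileupPlan:
    """Three-sample resequencing scenario: two strains, one later biofilm
    sample; the known MO-unique mutations near fixation in the MO
    samples, a block of deviations shared by all samples, and spurious
    sub-threshold noise."""
    rng = np.random.default_rng(seed)
    taken = {p for p, _, _ in MO_UNIQUE_VARIANTS}
    variants = [
        PlantedVariant(p, r, a, unique_frequency, 0.5, frozenset({"MO-batch", "MO-biofilm"}))
        for p, r, a in MO_UNIQUE_VARIANTS
    ]
    while len(variants) < len(MO_UNIQUE_VARIANTS) + n_shared:
        pos = int(rng.integers(1, 3_570_000))
        if pos in taken:
            continue
        taken.add(pos)
        ref, alt = rng.choice(4, size=2, replace=False)
        variants.append(
            PlantedVariant(pos, _BASES[ref], _BASES[alt], shared_frequency, 0.5,
                           frozenset(SAMPLES))
        )
    return PileupPlan(
        samples=SAMPLES,
        variants=tuple(variants),
        mean_depth=63.0,
        depth_model="poisson",
        noise_rate=noise_rate,
        seed=seed,
    )
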