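"""Read-frequency / strand-bias variant acceptance and cross-sample classification.

The acceptance rule treats a deviation from the reference as real when
at least ``min_frequency`` (default 10%) of the reads covering the site
support it and, when the supporting-read frequency is below
``high_frequency_cutoff`` (default 80%), the strand bias of the
supporting reads stays below ``max_strand_bias`` (default 70%).  Strand
bias is defined here as max(forward, reverse) / total supporting reads,
the simplest statistic consistent with "limited to less than 70%".

Passing calls are then compared across samples: a variant passing in
every sample is a shared deviation (most plausibly an error in the
reference assembly itself), one confined to the samples of a single
strain is strain-unique, and one appearing only in a designated
later/derived sample (e.g. a biofilm sampled after prolonged selection)
is emergent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codon import CdsRecord, annotate_genomic_variant
from .errors import DataError, UnsupportedVariantError

__all__ = [
    "VariantObservation",
    "FilterThresholds",
    "VariantCall",
    "CrossSampleClass",
    "estimate_frequency",
    "strand_bias",
    "apply_filter",
    "classify_across_samples",
    "screen_variants",
]

_NUC = frozenset("ACGTN")


@dataclass(frozen=True)
class VariantObservation:
    """Per-site, per-sample pileup summary with strand-split alt counts."""

    sample_id: str
    position: int  # 1-based genome coordinate
    ref_allele: str
    alt_allele: str
    depth: int
    alt_depth: int
    alt_fwd: int
    alt_rev: int

    def __post_init__(self):
        if self.position < 1:
            raise DataError(f"position must be 1-based positive, got {self.position}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if not allele or set(allele.upper()) - _NUC:
                raise DataError(f"bad {name} allele {allele!r} at {self.position}")
        if self.ref_allele.upper() == self.alt_allele.upper():
            raise DataError(f"ref == alt ({self.ref_allele}) at {self.position}")
        if self.depth < 0 or self.alt_depth < 0:
            raise DataError("negative depth")
        if self.alt_depth > self.depth:
            raise DataError(
                f"alt_depth {self.alt_depth} exceeds depth {self.depth} at {self.position}"
            )
        if self.alt_fwd + self.alt_rev != self.alt_depth:
            raise DataError(
                f"alt_fwd + alt_rev != alt_depth at {self.position} "
                f"({self.alt_fwd}+{self.alt_rev} != {self.alt_depth})"
            )

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_allele.upper(), self.alt_allele.upper())


@dataclass(frozen=True)
class FilterThresholds:
    min_frequency: float = 0.10
    high_frequency_cutoff: float = 0.80
    max_strand_bias: float = 0.70

    def __post_init__(self):
        if not 0 < self.min_frequency < self.high_frequency_cutoff <= 1:
            raise DataError("need 0 < min_frequency < high_frequency_cutoff <= 1")
        if not 0.5 <= self.max_strand_bias <= 1:
            raise DataError("max_strand_bias must be in [0.5, 1]")


@dataclass(frozen=True)
class VariantCall:
    observation: VariantObservation
    frequency: float
    strand_bias: Optional[float]  # None when alt_depth == 0
    passed: bool
    fail_reason: Optional[str]  # None | below_min_frequency | strand_biased

    def __post_init__(self):
        assert self.passed == (self.fail_reason is None)


def estimate_frequency(obs: VariantObservation) -> float:
    """Supporting-read frequency alt_depth / depth."""
    if obs.depth == 0:
        raise DataError(f"site {obs.position} is uncovered (depth 0)")
    return obs.alt_depth / obs.depth


def strand_bias(obs: VariantObservation) -> float:
    """max(alt_fwd, alt_rev) / alt_depth, in [0.5, 1]."""
    if obs.alt_depth == 0:
        raise DataError(f"strand bias undefined with no supporting reads at {obs.position}")
    return max(obs.alt_fwd, obs.alt_rev) / obs.alt_depth


def apply_filter(obs: VariantObservation, thresholds: FilterThresholds | None = None) -> VariantCall:
    """Apply the acceptance rule to one observation.

    passes  <=>  frequency >= min_frequency  and
                 (frequency >= high_frequency_cutoff  or  strand_bias < max_strand_bias)

    ``fail_reason`` reports the first violated clause in that order.
    """
    t = thresholds or FilterThresholds()
    freq = estimate_frequency(obs)
    bias = strand_bias(obs) if obs.alt_depth > 0 else None
    if freq < t.min_frequency:
        return VariantCall(obs, freq, bias, False, "below_min_frequency")
    if freq < t.high_frequency_cutoff and bias >= t.max_strand_bias:
        return VariantCall(obs, freq, bias, False, "strand_biased")
    return VariantCall(obs, freq, bias, True, None)


@dataclass(frozen=True)
class CrossSampleClass:
    key: tuple[int, str, str]  # (position, ref, alt)
    label: str  # shared_all | strain_unique | emergent | other
    strain: Optional[str]  # set for strain_unique
    frequency_by_sample: Mapping[str, float]
    passing_samples: frozenset[str]


def classify_across_samples(
    calls: Iterable[VariantCall],
    strain_of_sample: Mapping[str, str],
    later_samples: Iterable[str] = (),
) -> list[CrossSampleClass]:
    """Assign each variant key exactly one cross-sample label.

    * ``shared_all``: passing in every sample (reference-error signature);
    * ``emergent``: passing only in designated later samples;
    * ``strain_unique``: passing only in samples of exactly one strain;
    * ``other``: anything else, including keys with no passing call.
    """
    strain_of_sample = dict(strain_of_sample)
    if len(strain_of_sample) < 2:
        raise DataError("cross-sample classification needs at least 2 samples")
    later = set(later_samples)
    unknown_later = later - strain_of_sample.keys()
    if unknown_later:
        raise DataError(f"later samples not in strain map: {sorted(unknown_later)}")
    all_samples = set(strain_of_sample)

    by_key: dict[tuple, dict[str, VariantCall]] = {}
    for call in calls:
        sid = call.observation.sample_id
        if sid not in strain_of_sample:
            raise DataError(f"sample {sid!r} not in strain map")
        by_key.setdefault(call.observation.key, {})[sid] = call

    out: list[CrossSampleClass] = []
    for key in sorted(by_key):
        sample_calls = by_key[key]
        passing = frozenset(s for s, c in sample_calls.items() if c.passed)
        freqs = {s: c.frequency for s, c in sample_calls.items()}
        strains = {strain_of_sample[s] for s in passing}
        if passing == all_samples:
            label, strain = "shared_all", None
        elif passing and passing <= later:
            label, strain = "emergent", None
        elif len(strains) == 1:
            label, strain = "strain_unique", next(iter(strains))
        else:
            label, strain = "other", None
        out.append(CrossSampleClass(key, label, strain, freqs, passing))
    return out


def observations_from_table(table: pd.DataFrame) -> list[VariantObservation]:
    """Build observations from a pileup summary table with columns
    (sample, pos, ref, alt, depth, alt_depth, alt_fwd, alt_rev)."""
    required = {"sample", "pos", "ref", "alt", "depth", "alt_depth", "alt_fwd", "alt_rev"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"pileup table missing columns: {sorted(missing)}")
    return [
        VariantObservation(
            str(r.sample), int(r.pos), str(r.ref), str(r.alt),
            int(r.depth), int(r.alt_depth), int(r.alt_fwd), int(r.alt_rev),
        )
        for r in table.itertuples(index=False)
    ]


def screen_variants(
    pileup: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    strain_of_sample: Mapping[str, str] | None = None,
    later_samples: Iterable[str] = (),
    cds_records: Sequence[CdsRecord] = (),
    genome: Mapping[str, str] | None = None,
    near_fixed_cutoff: float = 0.90,
) -> pd.DataFrame:
    """End-to-end screen: filter, classify, and annotate codon consequences.

    Returns one row per variant key, sorted by position, with per-sample
    frequencies, the cross-sample label, a ``near_fixed`` flag (maximum
    passing frequency at or above ``near_fixed_cutoff``, the operational
    reading of "at or near 100% frequency"), and codon fields whenever a
    CDS covers the site and the alleles are length-preserving.
    """
    t = thresholds or FilterThresholds()
    if strain_of_sample is None:
        raise DataError("screen_variants requires a sample -> strain map")
    samples = list(strain_of_sample)
    columns = [
        "position", "ref", "alt", "label", "strain", "near_fixed",
        "gene_id", "aa_change", "synonymous",
        *[f"freq_{s}" for s in samples],
    ]
    if pileup.empty:
        return pd.DataFrame(columns=columns)

    obs = observations_from_table(pileup)
    calls = [apply_filter(o, t) for o in obs if o.depth > 0]
    classes = classify_across_samples(calls, strain_of_sample, later_samples)

    rows = []
    for cls in classes:
        pos, ref, alt = cls.key
        max_pass = max((cls.frequency_by_sample[s] for s in cls.passing_samples), default=0.0)
        gene_id = aa_change = ""
        synonymous: Optional[bool] = None
        if genome is not None and len(ref) == len(alt):
            for cds in cds_records:
                if cds.contains(pos, len(ref)):
                    try:
                        changes = annotate_genomic_variant(cds, genome, pos, ref, alt)
                    except UnsupportedVariantError:
                        break
                    gene_id = cds.gene_id
                    aa_change = ";".join(
                        f"{c.ref_aa}{c.residue_index}{c.alt_aa}" for c in changes
                    )
                    synonymous = all(c.synonymous for c in changes)
                    break
        row = {
            "position": pos, "ref": ref, "alt": alt,
            "label": cls.label, "strain": cls.strain or "",
            "near_fixed": bool(cls.passing_samples) and max_pass >= near_fixed_cutoff,
            "gene_id": gene_id, "aa_change": aa_change, "synonymous": synonymous,
        }
        for s in samples:
            row[f"freq_{s}"] = cls.frequency_by_sample.get(s, np.nan)
        rows.append(row)
    report = pd.DataFrame(rows, columns=columns)
    return report.sort_values("position", kind="stable").reset_index(drop=True)
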