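"""Proteome screen for type I secretion system (T1SS / RTX) cargo proteins.

T1SS substrates share little sequence identity but have recognisable
structural characteristics: they are unusually large, acidic (low
isoelectric point), contain few or no cysteines, carry the
hemolysin-type Ca2+-binding repeat signature (PROSITE PS00330),
glycine/alanine-rich stretches, and glycine/aspartate nonapeptide
repeats (GGXGXDXXX) close to the C terminus, which form the
calcium-binding beta-roll that the transporter recognises.  This module
extracts each feature and applies a configurable conjunction of
thresholds to nominate candidates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import DataError
from .prosite import MotifHit, PrositePattern, load_ps00330, parse_prosite_pattern, scan_pattern

__all__ = [
    "ProteinRecord",
    "CargoCriteria",
    "CargoReport",
    "PKA_SETS",
    "compute_pI",
    "count_cysteines",
    "find_glyala_segments",
    "screen_proteome",
    "NONAMER_PATTERN",
]

_CANONICAL = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; residues are normalised to uppercase.

    The 20 canonical letters plus ``X`` (unknown residue) are accepted.
    """

    id: str
    description: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise DataError(f"protein {self.id!r}: empty sequence")
        bad = set(seq) - _CANONICAL - {"X"}
        if bad:
            raise DataError(
                f"protein {self.id!r}: non-sequence characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


# Side-chain and terminal pKa tables. "bjellqvist" follows the
# Expasy-style model (with residue-specific terminal adjustments);
# "emboss" uses the EMBOSS iep defaults. The printed pI of a protein
# depends on which table produced it, so the set is selectable.
PKA_SETS: dict[str, dict] = {
    "bjellqvist": {
        "n_term": 7.5,
        "n_term_by_residue": {
            "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
            "T": 6.82, "V": 7.44, "E": 7.7,
        },
        "c_term": 3.55,
        "c_term_by_residue": {"D": 4.55, "E": 4.75},
        "acidic": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
        "basic": {"H": 5.98, "K": 10.0, "R": 12.0},
    },
    "emboss": {
        "n_term": 8.6,
        "n_term_by_residue": {},
        "c_term": 3.6,
        "c_term_by_residue": {},
        "acidic": {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
        "basic": {"H": 6.5, "K": 10.8, "R": 12.5},
    },
}


def net_charge(
    counts: Counter,
    ph: float,
    pka: dict,
    first_residue: str = "",
    last_residue: str = "",
    include_termini: bool = True,
) -> float:
    """Net charge at ``ph`` from Henderson-Hasselbalch terms.

    Positive groups contribute 1/(1+10^(pH-pKa)) each, negative groups
    -1/(1+10^(pKa-pH)) each.
    """
    q = 0.0
    if include_termini:
        nk = pka["n_term_by_residue"].get(first_residue, pka["n_term"])
        ck = pka["c_term_by_residue"].get(last_residue, pka["c_term"])
        q += 1.0 / (1.0 + 10.0 ** (ph - nk))
        q -= 1.0 / (1.0 + 10.0 ** (ck - ph))
    for aa, pk in pka["basic"].items():
        if counts.get(aa):
            q += counts[aa] / (1.0 + 10.0 ** (ph - pk))
    for aa, pk in pka["acidic"].items():
        if counts.get(aa):
            q -= counts[aa] / (1.0 + 10.0 ** (pk - ph))
    return q


def pi_from_counts(
    counts: Counter,
    pka: dict,
    first_residue: str = "",
    last_residue: str = "",
    include_termini: bool = True,
    tol: float = 1e-4,
) -> float:
    if not include_termini and not any(
        counts.get(aa) for aa in (*pka["acidic"], *pka["basic"])
    ):
        raise DataError("sequence has no ionizable groups and no termini model")
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(counts, mid, pka, first_residue, last_residue, include_termini)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def compute_pI(seq: str, pka_set: str = "bjellqvist", include_termini: bool = True) -> float:
    """Isoelectric point: the pH in [0, 14] where the net charge of the
    chain crosses zero, found by bisection to |Q| < 1e-4."""
    s = seq.upper()
    if not s:
        raise DataError("empty sequence")
    try:
        pka = PKA_SETS[pka_set]
    except KeyError:
        raise DataError(f"unknown pKa set {pka_set!r}; choose from {sorted(PKA_SETS)}")
    return pi_from_counts(Counter(s), pka, s[0], s[-1], include_termini)


def count_cysteines(seq: str) -> int:
    return seq.upper().count("C")


def find_glyala_segments(seq: str, window: int = 30, min_fraction: float = 0.4) -> list[tuple[int, int]]:
    """Maximal merged runs of length-``window`` windows whose combined
    Gly+Ala fraction is at least ``min_fraction`` (1-based inclusive)."""
    s = seq.upper()
    n = len(s)
    if window < 1:
        raise DataError("window must be positive")
    if window > n:
        raise DataError(f"window {window} exceeds sequence length {n}")
    is_ga = [1 if c in "GA" else 0 for c in s]
    count = sum(is_ga[:window])
    segments: list[list[int]] = []
    for i in range(n - window + 1):
        if i > 0:
            count += is_ga[i + window - 1] - is_ga[i - 1]
        if count / window >= min_fraction:
            start, end = i + 1, i + window
            if segments and start <= segments[-1][1] + 1:
                segments[-1][1] = max(segments[-1][1], end)
            else:
                segments.append([start, end])
    return [(a, b) for a, b in segments]


NONAMER_PATTERN = "G-G-x-G-x-D-x-x-x"


@dataclass(frozen=True)
class CargoCriteria:
    """Thresholds of the cargo screen.

    Defaults reflect the characteristics of known RTX-family adhesins:
    very large (>= 1000 aa), acidic (pI <= 4.5), cysteine-poor (<= 3),
    carrying the PS00330 signature, and with at least one GGXGXDXXX
    nonamer starting in the final quarter of the sequence.  In the
    nonamer only positions 1, 2 and 4 (Gly) and 6 (Asp) are constrained.
    """

    min_length: int = 1000
    max_pI: float = 4.5
    max_cysteines: int = 3
    require_ca_repeat: bool = True
    nonamer_pattern: str = NONAMER_PATTERN
    min_nonamers: int = 1
    c_term_window: float = 0.25
    glyala_window: int = 30
    glyala_min_fraction: float = 0.4
    pka_set: str = "bjellqvist"

    def __post_init__(self):
        if self.min_length < 1 or self.max_pI <= 0 or self.max_cysteines < 0:
            raise DataError("cargo criteria thresholds must be positive")
        if not 0 < self.c_term_window <= 1:
            raise DataError("c_term_window must be in (0, 1]")
        if self.min_nonamers < 0 or self.glyala_window < 1:
            raise DataError("cargo criteria thresholds must be positive")


@dataclass(frozen=True)
class CargoReport:
    protein_id: str
    length: int
    pI: float
    n_cys: int
    ps00330_hits: tuple[MotifHit, ...]
    nonamer_hits: tuple[MotifHit, ...]  # restricted to the C-terminal window
    glyala_segments: tuple[tuple[int, int], ...]
    verdict: str  # "candidate" | "rejected"
    failed_criteria: tuple[str, ...]

    def __post_init__(self):
        assert (self.verdict == "candidate") == (not self.failed_criteria)


def c_term_window_start(length: int, fraction: float) -> int:
    """First 1-based position inside the C-terminal window."""
    return length - int(fraction * length) + 1


def screen_protein(
    record: ProteinRecord,
    criteria: CargoCriteria,
    ca_pattern: PrositePattern | None = None,
    nonamer: PrositePattern | None = None,
) -> CargoReport:
    if ca_pattern is None:
        ca_pattern = load_ps00330()
    if nonamer is None:
        nonamer = parse_prosite_pattern(criteria.nonamer_pattern)
    seq = record.sequence
    n = len(seq)
    pi = compute_pI(seq, criteria.pka_set)
    n_cys = count_cysteines(seq)
    ca_hits = tuple(scan_pattern(seq, ca_pattern, record.id))
    win_start = c_term_window_start(n, criteria.c_term_window)
    nonamer_hits = tuple(
        h for h in scan_pattern(seq, nonamer, record.id) if h.start >= win_start
    )
    glyala = (
        tuple(find_glyala_segments(seq, criteria.glyala_window, criteria.glyala_min_fraction))
        if n >= criteria.glyala_window
        else ()
    )

    failed: list[str] = []
    if n < criteria.min_length:
        failed.append("min_length")
    if pi > criteria.max_pI:
        failed.append("max_pI")
    if n_cys > criteria.max_cysteines:
        failed.append("max_cysteines")
    if criteria.require_ca_repeat and not ca_hits:
        failed.append("ca_repeat")
    if len(nonamer_hits) < criteria.min_nonamers:
        failed.append("c_terminal_nonamers")
    verdict = "candidate" if not failed else "rejected"
    return CargoReport(
        record.id, n, pi, n_cys, ca_hits, nonamer_hits, glyala, verdict, tuple(failed)
    )


def screen_proteome(
    records: list[ProteinRecord],
    criteria: CargoCriteria | None = None,
    ca_pattern: PrositePattern | None = None,
) -> list[CargoReport]:
    """Screen every record; reports are returned in input order and are
    independent of that order record-by-record."""
    if criteria is None:
        criteria = CargoCriteria()
    if ca_pattern is None:
        ca_pattern = load_ps00330()
    nonamer = parse_prosite_pattern(criteria.nonamer_pattern)
    return [screen_protein(r, criteria, ca_pattern, nonamer) for r in records]
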