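"""Readers and writers shared across the pipeline.

FASTA goes through Biopython, GFF3 through gffutils, the optional VCF
input adapter through cyvcf2.  Tabular outputs are TSV with ``#``
comment headers carrying the tool version, seed and config digest; all
user-facing coordinates are 1-based inclusive (BED exports, when
selected, convert centrally to 0-based half-open).
"""

from __future__ import annotations

import hashlib

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .cargo import ProteinRecord
from .codon import CdsRecord
from .errors import DataError
from .variants import VariantCall

_NUC_OK = frozenset("ACGTN")


from dataclasses import dataclass


@dataclass(frozen=True)
class NucleotideRecord:
    """A nucleotide FASTA record (A/C/G/T/N, uppercase-normalised)."""

    id: str
    description: str
    sequence: str


def read_fasta(path: str | Path, kind: str = "protein") -> list:
    """Read a multi-record FASTA; duplicate IDs and non-sequence
    characters are explicit errors; lowercase residues are normalised to
    uppercase with a flag preserved in the description."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        desc = rec.description[len(rec.id):].strip()
        if raw != raw.upper():
            desc = (desc + " lowercase_normalized=true").strip()
        if kind == "nucleotide":
            bad = set(raw.upper()) - _NUC_OK
            if bad:
                raise DataError(f"record {rec.id!r}: non-nucleotide characters {sorted(bad)}")
            records.append(NucleotideRecord(rec.id, desc, raw.upper()))
        else:
            records.append(ProteinRecord(rec.id, desc, raw))
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return records


def read_genome(path: str | Path) -> dict[str, str]:
    return {r.id: r.sequence for r in read_fasta(path, kind="nucleotide")}


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_gff3_cds(path: str | Path) -> list[CdsRecord]:
    """CDS intervals from a GFF3 file, multi-segment CDS joined in strand
    order (validation of strand, ordering and overlap happens in
    :class:`CdsRecord`)."""
    import gffutils

    path = Path(path)
    if not path.exists():
        raise DataError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    groups: dict[tuple, list] = {}
    for feat in db.features_of_type("CDS"):
        if feat.start > feat.end:
            raise DataError(f"CDS at {feat.start}-{feat.end}: start > end")
        gene_id = (
            feat.attributes.get("Parent", [None])[0]
            or feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("gene_id", [None])[0]
        )
        if gene_id is None:
            raise DataError(f"CDS at {feat.start}-{feat.end} lacks Parent/ID/gene_id")
        groups.setdefault((gene_id, feat.seqid, feat.strand), []).append(
            (feat.start, feat.end)
        )
    out = []
    for (gene_id, seqid, strand), segments in groups.items():
        rec = CdsRecord(gene_id, seqid, strand, tuple(segments))
        if rec.length % 3 != 0:
            import warnings

            warnings.warn(
                f"CDS {gene_id!r} length {rec.length} is not a multiple of 3",
                stacklevel=2,
            )
        out.append(rec)
    out.sort(key=lambda r: (r.seqid, r.segments[0][0]))
    if not out:
        raise DataError(f"no CDS features in {path}")
    return out


# ---------------------------------------------------------------------------
# TSV with provenance headers

def output_header(seed: int | None = None, config_digest: str | None = None) -> list[str]:
    parts = [f"straindrift v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_digest is not None:
        parts.append(f"config_digest={config_digest}")
    return ["# " + " ".join(parts)]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_digest: str | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in output_header(seed, config_digest):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"table not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # malformed TSV
        raise DataError(f"could not parse {path}: {exc}") from exc


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def to_bed_interval(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Central 1-based inclusive -> 0-based half-open conversion."""
    return start_1based - 1, end_1based


# ---------------------------------------------------------------------------
# minimal VCF v4.x subset

_VCF_HEADER = """##fileformat=VCFv4.2
##source=straindrift_v{version}
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt-supporting read depth">
##INFO=<ID=ADF,Number=1,Type=Integer,Description="Alt-supporting reads, forward strand">
##INFO=<ID=ADR,Number=1,Type=Integer,Description="Alt-supporting reads, reverse strand">
##FILTER=<ID=below_min_frequency,Description="Supporting-read frequency below the minimum">
##FILTER=<ID=strand_biased,Description="Sub-fixation variant with excessive strand bias">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Sequence[VariantCall], path: str | Path, chrom: str = "chr") -> None:
    """Minimal single-sample VCF with the filter verdict in FILTER."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(version=__version__))
        for c in sorted(calls, key=lambda c: c.observation.position):
            o = c.observation
            filt = "PASS" if c.passed else c.fail_reason
            info = f"DP={o.depth};AD={o.alt_depth};ADF={o.alt_fwd};ADR={o.alt_rev}"
            fh.write(
                f"{chrom}\t{o.position}\t.\t{o.ref_allele}\t{o.alt_allele}\t.\t{filt}\t{info}\n"
            )


def read_vcf_observations(path: str | Path, sample_id: str = "sample") -> pd.DataFrame:
    """Read a minimal VCF into the pileup-table schema; unknown INFO keys
    are ignored.  Records without DP/AD are skipped as unusable."""
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise DataError(f"VCF file not found: {path}")
    rows = []
    for v in VCF(str(path)):
        dp = v.INFO.get("DP")
        ad = v.INFO.get("AD")
        if dp is None or ad is None:
            continue
        adf = v.INFO.get("ADF")
        adr = v.INFO.get("ADR")
        if adf is None and adr is None:
            adf, adr = ad, 0  # strand split unavailable; worst-case bias
        elif adf is None:
            adf = ad - adr
        elif adr is None:
            adr = ad - adf
        alt = v.ALT[0] if v.ALT else None
        if alt is None:
            continue
        rows.append((sample_id, v.POS, v.REF, alt, int(dp), int(ad), int(adf), int(adr)))
    return pd.DataFrame(
        rows,
        columns=["sample", "pos", "ref", "alt", "depth", "alt_depth", "alt_fwd", "alt_rev"],
    )
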