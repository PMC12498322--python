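"""Plastid-bin identification from contig classifications.

Contigs of a metagenome assembly arrive pre-classified (a Tiara-style
table of contig id → class label) and pre-binned (metaBAT2-style per-bin
FASTA files or a two-column membership table).  A bin is flagged a
*probable plastid bin* when the fraction of its span — nucleotides, not
contig counts — classified as plastid strictly exceeds a threshold
(default 0.90).  Bins below a minimum span (default 50 kb, the reduced
bin size used at binning time) are still reported but carry a sub-span
flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_LABELS",
    "ContigClassification",
    "BinRecord",
    "load_contig_classifications",
    "load_bin_membership",
    "contig_lengths_from_fasta",
    "classify_bins",
    "write_bins_table",
]

CLASS_LABELS = (
    "plastid",
    "mitochondrion",
    "bacteria",
    "archaea",
    "eukarya",
    "prokarya",
    "unknown",
)

# case-insensitive synonyms accepted from classifier output;
# "organelle" is ambiguous between plastid and mitochondrion -> unknown
_LABEL_SYNONYMS = {
    "plastid": "plastid",
    "chloroplast": "plastid",
    "mitochondrion": "mitochondrion",
    "mitochondria": "mitochondrion",
    "bacteria": "bacteria",
    "bacterium": "bacteria",
    "archaea": "archaea",
    "archaeon": "archaea",
    "eukarya": "eukarya",
    "eukaryote": "eukarya",
    "eukaryota": "eukarya",
    "prokarya": "prokarya",
    "prokaryote": "prokarya",
    "unknown": "unknown",
    "unk": "unknown",
}

_ID_COLUMNS = ("contig_id", "sequence_id", "sequence id", "seq_id")
_CLASS_COLUMNS = ("class_label", "class", "classification", "class_snd_stage", "class_fst_stage")
_LENGTH_COLUMNS = ("length_bp", "length", "contig_length")


@dataclass(frozen=True)
class ContigClassification:
    contig_id: str
    class_label: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"invalid class label {self.class_label!r}")
        if self.length_bp < 1:
            raise ValueError(f"contig {self.contig_id} has length < 1")


@dataclass(frozen=True)
class BinRecord:
    bin_id: str
    contig_ids: tuple[str, ...]
    span_bp: int
    plastid_span_bp: int
    plastid_contig_count: int
    plastid_fraction: float  # by nucleotides; drives the retention rule
    plastid_contig_fraction: float  # by contig count; informational
    is_probable_plastid: bool
    sub_span: bool

    @property
    def n_contigs(self) -> int:
        return len(self.contig_ids)


def normalize_label(raw: str) -> str:
    label = _LABEL_SYNONYMS.get(raw.strip().lower())
    if label is None:
        logger.warning("unrecognized contig class label %r mapped to 'unknown'", raw)
        return "unknown"
    return label


def _pick_column(df: pd.DataFrame, candidates: Sequence[str]) -> str | None:
    lower = {c.lower(): c for c in df.columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    return None


def load_contig_classifications(
    path: str | Path,
    lengths: Mapping[str, int] | None = None,
) -> list[ContigClassification]:
    """Read a Tiara-style classification TSV.

    Contig lengths come from a ``length`` column if present, otherwise
    from the ``lengths`` mapping (e.g. built with
    :func:`contig_lengths_from_fasta`).  Labels are normalized
    case-insensitively; unrecognized labels become ``unknown`` with a
    logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = _pick_column(df, _ID_COLUMNS)
    class_col = _pick_column(df, _CLASS_COLUMNS)
    if id_col is None or class_col is None:
        raise ValueError(
            f"classification table {path} needs a contig id column "
            f"({_ID_COLUMNS}) and a class column ({_CLASS_COLUMNS})"
        )
    if df[id_col].duplicated().any():
        dupes = sorted(df.loc[df[id_col].duplicated(), id_col].unique())
        raise ValueError(f"duplicate contig ids in {path}: {dupes[:5]}")
    length_col = _pick_column(df, _LENGTH_COLUMNS)
    records = []
    for _, row in df.iterrows():
        cid = str(row[id_col])
        if length_col is not None:
            length = int(row[length_col])
        else:
            if lengths is None or cid not in lengths:
                raise ValueError(
                    f"no length available for contig {cid!r}: supply a length "
                    "column or a lengths mapping"
                )
            length = int(lengths[cid])
        records.append(ContigClassification(cid, normalize_label(row[class_col]), length))
    return records


def contig_lengths_from_fasta(path: str | Path) -> dict[str, int]:
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_bin_membership(path_or_dir: str | Path) -> dict[str, list[str]]:
    """Read bin membership from per-bin FASTAs or a two-column TSV.

    Directory form: each ``*.fa``/``*.fasta`` file is one bin (bin id =
    file stem).  TSV form: header with columns ``contig_id``, ``bin_id``.
    A contig assigned to two bins is a format error.  Contigs absent from
    the mapping are implicitly the unbinned pool.
    """
    path = Path(path_or_dir)
    membership: dict[str, list[str]] = {}
    seen: dict[str, str] = {}

    def _add(bin_id: str, contig_id: str) -> None:
        if contig_id in seen:
            raise ValueError(
                f"contig {contig_id!r} assigned to both {seen[contig_id]!r} "
                f"and {bin_id!r}"
            )
        seen[contig_id] = bin_id
        membership.setdefault(bin_id, []).append(contig_id)

    if path.is_dir():
        fastas = sorted(
            f for f in path.iterdir() if f.suffix.lower() in (".fa", ".fasta", ".fna")
        )
        if not fastas:
            logger.warning("no FASTA files found in bin directory %s", path)
        for f in fastas:
            for rec in SeqIO.parse(str(f), "fasta"):
                _add(f.stem, rec.id)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "contig_id" not in df.columns or "bin_id" not in df.columns:
            raise ValueError(
                f"membership table {path} needs columns contig_id and bin_id"
            )
        for _, row in df.iterrows():
            _add(str(row["bin_id"]), str(row["contig_id"]))
    return membership


def classify_bins(
    membership: Mapping[str, Sequence[str]],
    classifications: Iterable[ContigClassification],
    min_plastid_content: float = 0.90,
    min_bin_span_bp: int = 50_000,
) -> list[BinRecord]:
    """Apply the probable-plastid-bin retention rule to every bin.

    ``plastid_fraction`` is the nucleotide fraction of the bin's span on
    contigs classified as plastid; a bin is probable-plastid only when
    that fraction *strictly exceeds* ``min_plastid_content``.  Output is
    ordered by bin id.
    """
    by_id = {c.contig_id: c for c in classifications}
    missing = sorted(
        cid for contigs in membership.values() for cid in contigs if cid not in by_id
    )
    if missing:
        raise ValueError(f"binned contigs missing a classification: {missing[:10]}")
    records = []
    for bin_id in sorted(membership):
        contigs = [by_id[cid] for cid in membership[bin_id]]
        span = sum(c.length_bp for c in contigs)
        plastid = [c for c in contigs if c.class_label == "plastid"]
        p_span = sum(c.length_bp for c in plastid)
        frac = p_span / span if span else 0.0
        records.append(
            BinRecord(
                bin_id=bin_id,
                contig_ids=tuple(c.contig_id for c in contigs),
                span_bp=span,
                plastid_span_bp=p_span,
                plastid_contig_count=len(plastid),
                plastid_fraction=frac,
                plastid_contig_fraction=len(plastid) / len(contigs) if contigs else 0.0,
                is_probable_plastid=frac > min_plastid_content,
                sub_span=span < min_bin_span_bp,
            )
        )
    return records


def write_bins_table(records: Sequence[BinRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "bin_id": r.bin_id,
                "span_bp": r.span_bp,
                "n_contigs": r.n_contigs,
                "n_plastid_contigs": r.plastid_contig_count,
                "plastid_span_bp": r.plastid_span_bp,
                "plastid_fraction": round(r.plastid_fraction, 6),
                "probable_plastid": r.is_probable_plastid,
                "sub_span_flag": r.sub_span,
            }
            for r in records
        ],
        columns=[
            "bin_id",
            "span_bp",
            "n_contigs",
            "n_plastid_contigs",
            "plastid_span_bp",
            "plastid_fraction",
            "probable_plastid",
            "sub_span_flag",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
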