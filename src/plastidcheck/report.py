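"""Per-sample summary reports for probable plastid bins.

Joins bin records with completeness predictions, contig-level taxonomy
(CAT-style tables) and marker-gene hits (hmmer domain tables for rbcL,
barrnap-style GFF3 for rRNA loci) into one row per probable plastid bin.
Missing side tables leave their columns empty; they never fail the join.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bins import BinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PlastidBinReportRow",
    "MarkerLocus",
    "MARKER_NAMES",
    "build_report",
    "write_report",
    "ingest_taxonomy",
    "ingest_markers",
    "extract_marker_fasta",
]

MARKER_NAMES = ("rbcL", "rRNA_16S-like", "rRNA_23S-like", "rRNA_5S-like")

# barrnap reports bacterial-style rRNA names for plastids (endosymbiotic
# origin); map the usual product names onto the report vocabulary
_RRNA_NAME_MAP = {
    "16s": "rRNA_16S-like",
    "16s_rrna": "rRNA_16S-like",
    "23s": "rRNA_23S-like",
    "23s_rrna": "rRNA_23S-like",
    "5s": "rRNA_5S-like",
    "5s_rrna": "rRNA_5S-like",
}


@dataclass(frozen=True)
class PlastidBinReportRow:
    sample_id: str
    bin_id: str
    span_bp: int
    n_contigs: int
    n_plastid_contigs: int
    completeness_percent: float | None
    taxonomy: str | None
    markers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.completeness_percent is not None and not (
            0.0 <= self.completeness_percent <= 100.0
        ):
            raise ValueError("completeness must be in [0, 100]")


@dataclass(frozen=True)
class MarkerLocus:
    """A marker-gene locus with 1-based inclusive coordinates."""

    marker: str
    contig_id: str
    start: int  # 1-based
    end: int    # inclusive
    strand: str  # "+" or "-"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def build_report(
    bins: Sequence[BinRecord],
    predictions: Mapping[str, float] | None = None,
    taxonomy: Mapping[str, str] | None = None,
    markers: Mapping[str, frozenset[str]] | None = None,
    sample_id: str = "sample",
) -> list[PlastidBinReportRow]:
    """One report row per probable plastid bin.

    ``predictions`` maps bin id → completeness percent; a prediction for
    a bin id not among the bins is dropped with a warning.  Absent side
    tables leave the corresponding fields empty.
    """
    predictions = dict(predictions or {})
    known = {b.bin_id for b in bins}
    for stray in sorted(set(predictions) - known):
        logger.warning("prediction for unknown bin %r dropped", stray)
        predictions.pop(stray)
    rows = []
    for b in sorted(bins, key=lambda r: r.bin_id):
        if not b.is_probable_plastid:
            continue
        rows.append(
            PlastidBinReportRow(
                sample_id=sample_id,
                bin_id=b.bin_id,
                span_bp=b.span_bp,
                n_contigs=b.n_contigs,
                n_plastid_contigs=b.plastid_contig_count,
                completeness_percent=predictions.get(b.bin_id),
                taxonomy=(taxonomy or {}).get(b.bin_id),
                markers=frozenset((markers or {}).get(b.bin_id, frozenset())),
            )
        )
    return rows


_REPORT_COLUMNS = [
    "sample_id",
    "bin_id",
    "span_bp",
    "n_contigs",
    "n_plastid_contigs",
    "completeness_percent",
    "taxonomy",
    "markers",
]


def write_report(rows: Sequence[PlastidBinReportRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "bin_id": r.bin_id,
                "span_bp": r.span_bp,
                "n_contigs": r.n_contigs,
                "n_plastid_contigs": r.n_plastid_contigs,
                "completeness_percent": (
                    "" if r.completeness_percent is None
                    else f"{r.completeness_percent:.1f}"
                ),
                "taxonomy": r.taxonomy or "",
                "markers": ",".join(sorted(r.markers)),
            }
            for r in rows
        ],
        columns=_REPORT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# --- taxonomy -------------------------------------------------------------

def _split_lineage(text: str) -> list[str]:
    parts = [p.strip() for p in str(text).split(";")]
    return [p for p in parts if p]


def ingest_taxonomy(
    path: str | Path,
    membership: Mapping[str, Sequence[str]],
    contig_lengths: Mapping[str, int],
) -> dict[str, str]:
    """Aggregate contig-level CAT-style lineages into bin-level calls.

    For each bin, the call is the most specific lineage prefix supported
    by a span-weighted majority (> 50%) of the bin's classified contigs;
    with no majority at any depth the deepest common ancestor of all
    classified contigs is reported.  Rows with no parseable lineage are
    skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lower = {c.lower(): c for c in df.columns}
    id_col = next(
        (lower[c] for c in ("contig_id", "# contig", "contig", "sequence_id") if c in lower),
        df.columns[0],
    )
    lin_col = next(
        (lower[c] for c in ("lineage", "lineage names", "classification") if c in lower),
        None,
    )
    if lin_col is None:
        lin_col = df.columns[-1]
    contig_lineage: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        lineage = _split_lineage(row[lin_col])
        if not lineage:
            logger.warning("unparseable lineage for contig %r skipped", row[id_col])
            continue
        contig_lineage[str(row[id_col])] = lineage

    out: dict[str, str] = {}
    for bin_id, contigs in membership.items():
        entries = [
            (contig_lineage[c], contig_lengths.get(c, 1))
            for c in contigs
            if c in contig_lineage
        ]
        if not entries:
            continue
        total = sum(w for _, w in entries)
        max_depth = max(len(lin) for lin, _ in entries)
        call: list[str] | None = None
        for depth in range(max_depth, 0, -1):
            weights: dict[tuple[str, ...], int] = {}
            for lin, w in entries:
                if len(lin) >= depth:
                    weights[tuple(lin[:depth])] = weights.get(tuple(lin[:depth]), 0) + w
            best = max(weights.items(), key=lambda kv: kv[1], default=None)
            if best is not None and best[1] * 2 > total:
                call = list(best[0])
                break
        if call is None:
            # deepest common ancestor of all classified contigs
            call = []
            for parts in zip(*(lin for lin, _ in entries)):
                if len(set(parts)) == 1:
                    call.append(parts[0])
                else:
                    break
        if call:
            out[bin_id] = ";".join(call)
    return out


# --- markers --------------------------------------------------------------

def _contig_to_bin(membership: Mapping[str, Sequence[str]]) -> dict[str, str]:
    return {c: b for b, contigs in membership.items() for c in contigs}


def parse_hmmer_domtbl(path: str | Path) -> list[MarkerLocus]:
    """Parse an hmmer ``--domtblout`` table into marker loci.

    Columns are whitespace-delimited; the target is the contig, the
    query is the profile (marker) name, and the envelope coordinates
    (columns 20–21, 1-based inclusive) locate the hit.  Protein-profile
    hits carry no strand, recorded as '+'.
    """
    loci = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 21:
            logger.warning("short hmmer table row skipped: %r", line[:60])
            continue
        loci.append(
            MarkerLocus(
                marker=f[3],
                contig_id=f[0],
                start=int(f[19]),
                end=int(f[20]),
                strand="+",
            )
        )
    return loci


def parse_rrna_gff(path: str | Path) -> list[MarkerLocus]:
    """Parse barrnap-style GFF3 rRNA predictions into marker loci.

    Coordinates are GFF3 1-based inclusive; the rRNA name is read from
    the ``Name=`` attribute (or ``product=``) and mapped onto the report
    vocabulary; unmapped names pass through unchanged so the vocabulary
    stays open-ended.
    """
    loci = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        raw = attrs.get("Name") or attrs.get("product") or f[2]
        key = raw.strip().lower().replace(" ribosomal rna", "_rrna").replace(" ", "_")
        marker = _RRNA_NAME_MAP.get(key, raw.strip())
        loci.append(
            MarkerLocus(
                marker=marker,
                contig_id=f[0],
                start=int(f[3]),
                end=int(f[4]),
                strand=f[6] if f[6] in ("+", "-") else "+",
            )
        )
    return loci


def ingest_markers(
    membership: Mapping[str, Sequence[str]],
    hmm_table: str | Path | None = None,
    rrna_table: str | Path | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> tuple[dict[str, frozenset[str]], list[MarkerLocus]]:
    """Collect marker presence per bin plus the locus records.

    Loci whose coordinates exceed the contig length (when lengths are
    known) are skipped with a warning.  Both tables absent yields empty
    marker sets.
    """
    loci: list[MarkerLocus] = []
    if hmm_table is not None:
        loci.extend(parse_hmmer_domtbl(hmm_table))
    if rrna_table is not None:
        loci.extend(parse_rrna_gff(rrna_table))
    if contig_lengths:
        kept = []
        for loc in loci:
            limit = contig_lengths.get(loc.contig_id)
            if limit is not None and (loc.end > limit or loc.start < 1):
                logger.warning(
                    "locus %s on %s (%d-%d) exceeds contig length %d; skipped",
                    loc.marker, loc.contig_id, loc.start, loc.end, limit,
                )
                continue
            kept.append(loc)
        loci = kept
    c2b = _contig_to_bin(membership)
    sets: dict[str, set[str]] = {}
    for loc in loci:
        bin_id = c2b.get(loc.contig_id)
        if bin_id is not None:
            sets.setdefault(bin_id, set()).add(loc.marker)
    return {b: frozenset(s) for b, s in sets.items()}, loci


def extract_marker_fasta(
    loci: Sequence[MarkerLocus],
    assembly_fasta: str | Path,
    out_path: str | Path,
) -> int:
    """Write marker locus sequences, reverse-complementing minus-strand hits.

    Returns the number of sequences written.
    """
    contigs = SeqIO.to_dict(SeqIO.parse(str(assembly_fasta), "fasta"))
    records = []
    for loc in loci:
        if loc.contig_id not in contigs:
            logger.warning("contig %s not in assembly; locus skipped", loc.contig_id)
            continue
        seq = contigs[loc.contig_id].seq[loc.start - 1 : loc.end]
        if loc.strand == "-":
            seq = Seq(str(seq)).reverse_complement()
        records.append(
            SeqRecord(
                Seq(str(seq)),
                id=f"{loc.marker}|{loc.contig_id}|{loc.start}-{loc.end}({loc.strand})",
                description="",
            )
        )
    SeqIO.write(records, str(out_path), "fasta")
    return len(records)
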