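"""Synthetic fixtures: toy samples and the bundled module catalog.

Everything the pipeline consumes — assembly FASTA, contig classification
table, bin membership, KO annotation tables — can be generated here with
known ground truth, so the full workflow is testable with no external
tools or downloads.  Fixture sequences are uniform-random nucleotides:
classification is consumed from tables, never computed from sequence, so
realistic composition would buy nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .kegg_modules import ModuleDefinition, load_module_catalog
from .simulator import derive_seed

__all__ = [
    "BinComposition",
    "FixtureSpec",
    "generate_toy_sample",
    "random_fixture_spec",
    "bundled_module_catalog",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class BinComposition:
    """Per-class nucleotide totals and contig counts for one bin."""

    bin_id: str
    # class label -> (total bp, contig count)
    classes: tuple[tuple[str, tuple[int, int]], ...]

    @property
    def span_bp(self) -> int:
        return sum(bp for _, (bp, _) in self.classes)

    @property
    def plastid_fraction(self) -> float:
        p = sum(bp for label, (bp, _) in self.classes if label == "plastid")
        return p / self.span_bp if self.span_bp else 0.0


@dataclass(frozen=True)
class FixtureSpec:
    bins: tuple[BinComposition, ...]
    unbinned: tuple[tuple[str, tuple[int, int]], ...] = ()
    seed: int = 0
    sample_id: str = "toy_sample"


def _random_contig_lengths(rng: np.random.Generator, total_bp: int, n: int) -> list[int]:
    if n == 1:
        return [total_bp]
    # split total_bp into n parts of at least 100 bp each
    cuts = np.sort(rng.choice(total_bp - 100 * n, size=n - 1, replace=False))
    parts = np.diff(np.concatenate([[0], cuts, [total_bp - 100 * n]])) + 100
    return [int(x) for x in parts]


def _write_fasta(path: Path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for cid, seq in seqs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def generate_toy_sample(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write a complete toy sample and return a manifest with ground truth.

    Emits ``assembly.fasta``, ``classifications.tsv`` (contig id, class,
    length), ``bin_membership.tsv`` and ``ground_truth.json`` (per-bin
    true plastid fraction and span).  Byte-reproducible for a given
    spec/seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows: list[tuple[str, str, int]] = []
    membership_rows: list[tuple[str, str]] = []
    seqs: dict[str, str] = {}
    counter = 0

    def _emit(label: str, bp: int, n: int, bin_id: str | None, key: str) -> None:
        nonlocal counter
        rng = np.random.default_rng(derive_seed(spec.seed, key, label))
        for length in _random_contig_lengths(rng, bp, n):
            cid = f"contig_{counter:05d}"
            counter += 1
            seqs[cid] = "".join(_BASES[rng.integers(0, 4, size=length)])
            rows.append((cid, label, length))
            if bin_id is not None:
                membership_rows.append((cid, bin_id))

    for comp in spec.bins:
        for label, (bp, n) in comp.classes:
            _emit(label, bp, n, comp.bin_id, comp.bin_id)
    for label, (bp, n) in spec.unbinned:
        _emit(label, bp, n, None, "unbinned")

    _write_fasta(outdir / "assembly.fasta", seqs)
    with open(outdir / "classifications.tsv", "w") as fh:
        fh.write("contig_id\tclass_label\tlength_bp\n")
        for cid, label, length in rows:
            fh.write(f"{cid}\t{label}\t{length}\n")
    with open(outdir / "bin_membership.tsv", "w") as fh:
        fh.write("contig_id\tbin_id\n")
        for cid, bin_id in membership_rows:
            fh.write(f"{cid}\t{bin_id}\n")
    truth = {
        "sample_id": spec.sample_id,
        "seed": spec.seed,
        "bins": {
            comp.bin_id: {
                "span_bp": comp.span_bp,
                "plastid_fraction": comp.plastid_fraction,
            }
            for comp in spec.bins
        },
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "assembly": str(outdir / "assembly.fasta"),
        "classifications": str(outdir / "classifications.tsv"),
        "bin_membership": str(outdir / "bin_membership.tsv"),
        "ground_truth": truth,
    }


def random_fixture_spec(seed: int, n_bins: int | None = None) -> FixtureSpec:
    """Draw a random toy-sample composition with known plastid fractions."""
    rng = np.random.default_rng(seed)
    if n_bins is None:
        n_bins = int(rng.integers(1, 5))
    bins = []
    for b in range(n_bins):
        plastid_bp = int(rng.integers(5_000, 120_000))
        other_label = str(rng.choice(["bacteria", "mitochondrion", "eukarya", "unknown"]))
        other_bp = int(rng.integers(0, 60_000))
        classes: list[tuple[str, tuple[int, int]]] = [
            ("plastid", (plastid_bp, int(rng.integers(1, 4)))),
        ]
        if other_bp >= 500:
            classes.append((other_label, (other_bp, int(rng.integers(1, 3)))))
        bins.append(BinComposition(f"bin_{b:03d}", tuple(classes)))
    unbinned = (("bacteria", (int(rng.integers(1_000, 20_000)), 2)),)
    return FixtureSpec(tuple(bins), unbinned, seed=seed)


def bundled_module_catalog() -> list[ModuleDefinition]:
    """The shipped 36-module synthetic test catalog.

    Stable within a major version; exercises every grammar feature
    (alternatives, complexes, optional members, nested groups).
    """
    ref = resources.files("plastidcheck").joinpath("data/module_catalog.tsv")
    with resources.as_file(ref) as path:
        return load_module_catalog(path)
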