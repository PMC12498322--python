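"""Simulation of partial genomes by annotation subsampling.

Training data for the completeness regressor are made by taking a
reference genome's KO annotation multiset and drawing a uniformly random
sub-multiset without replacement.  A genome at nominal completeness *f*
keeps ``round(f * total)`` annotation tokens (round half away from
zero); the sampling unit is the individual gene-level annotation token,
so a KO annotated three times contributes three tokens and can survive
partially.  This mirrors losing genes from an incomplete assembly, not
losing whole pathways.

The module also synthesizes fully artificial plastid-like and
mitochondria-like reference profiles so the whole training/evaluation
pipeline runs offline with known ground truth.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kegg_modules import (
    KOProfile,
    ModuleCoverageVector,
    ModuleDefinition,
    coverage_vector,
)

__all__ = [
    "SimulatedExample",
    "LabeledExample",
    "LabeledDataset",
    "DEFAULT_TRAINING_FRACTIONS",
    "TEST_GRID_FRACTIONS",
    "derive_seed",
    "subsample_profile",
    "make_training_grid",
    "filter_training_references",
    "synthesize_reference_profiles",
    "save_dataset",
    "load_dataset",
]

# 0–100% in 5% increments: the training grid
DEFAULT_TRAINING_FRACTIONS: tuple[float, ...] = tuple(
    round(i * 0.05, 2) for i in range(21)
)
# 10–100% in 10% increments: the held-out evaluation grid
TEST_GRID_FRACTIONS: tuple[float, ...] = tuple(round(i * 0.1, 1) for i in range(1, 11))


@dataclass(frozen=True)
class SimulatedExample:
    source_genome_id: str
    expected_completeness: float  # percent in [0, 100]
    profile: KOProfile
    replicate_index: int
    seed: int


@dataclass(frozen=True)
class LabeledExample:
    source_genome_id: str
    expected_completeness: float  # percent
    features: ModuleCoverageVector


@dataclass
class LabeledDataset:
    examples: list[LabeledExample]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.examples)

    @property
    def source_genome_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ex in self.examples:
            seen.setdefault(ex.source_genome_id)
        return list(seen)

    @property
    def module_order(self) -> tuple[str, ...]:
        return self.examples[0].features.module_order

    def feature_matrix(self) -> np.ndarray:
        return np.asarray([ex.features.values for ex in self.examples], dtype=float)

    def labels(self) -> np.ndarray:
        return np.asarray([ex.expected_completeness for ex in self.examples], dtype=float)

    def subset(self, genome_ids: Sequence[str]) -> "LabeledDataset":
        keep = set(genome_ids)
        return LabeledDataset(
            [ex for ex in self.examples if ex.source_genome_id in keep],
            dict(self.provenance),
        )


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed from a master seed and arbitrary labels.

    Uses blake2b over the repr of the inputs so grids are reproducible
    under partial re-runs and across processes (Python's builtin hash is
    salted per interpreter).  Result is in [0, 2^31).
    """
    key = repr((int(master_seed),) + parts).encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def subsample_profile(profile: KOProfile, fraction: float, seed: int) -> KOProfile:
    """Uniform sub-multiset of the profile's annotation tokens.

    Keeps ``round(fraction * total)`` tokens (half away from zero),
    sampled without replacement; deterministic for a given seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    tokens = profile.tokens()
    k = _round_half_away(fraction * len(tokens))
    if k >= len(tokens):
        return KOProfile(profile.genome_id, dict(profile.counts))
    if k == 0:
        return KOProfile(profile.genome_id, {})
    rng = np.random.default_rng(seed)
    kept = rng.choice(len(tokens), size=k, replace=False)
    counts: dict[str, int] = {}
    for i in kept:
        ko = tokens[int(i)]
        counts[ko] = counts.get(ko, 0) + 1
    return KOProfile(profile.genome_id, counts)


def make_training_grid(
    profiles: Sequence[KOProfile],
    catalog: Sequence[ModuleDefinition],
    fractions: Sequence[float] = DEFAULT_TRAINING_FRACTIONS,
    replicates: int = 1,
    seed: int = 0,
    binary: bool = False,
) -> LabeledDataset:
    """Simulate a completeness grid and featurize it.

    For each profile × fraction × replicate a subsample is drawn with a
    derived per-cell seed, converted to a module-coverage vector, and
    labeled ``100 * fraction``.
    """
    if not profiles:
        raise ValueError("no reference profiles supplied")
    bad = [f for f in fractions if not 0.0 <= f <= 1.0]
    if bad:
        raise ValueError(f"fractions outside [0, 1]: {bad}")
    examples: list[LabeledExample] = []
    for p in profiles:
        for f in fractions:
            for r in range(replicates):
                cell_seed = derive_seed(seed, p.genome_id, float(f), r)
                sub = subsample_profile(p, f, cell_seed)
                feats = coverage_vector(sub, catalog, binary=binary)
                examples.append(
                    LabeledExample(p.genome_id, round(100.0 * f, 6), feats)
                )
    provenance = {
        "fractions": [float(f) for f in fractions],
        "replicates": int(replicates),
        "seed": int(seed),
        "n_references": len(profiles),
        "binary": bool(binary),
    }
    return LabeledDataset(examples, provenance)


def filter_training_references(
    profiles: Sequence[KOProfile],
    spans: Mapping[str, int],
    min_span_bp: int = 94_000,
) -> list[KOProfile]:
    """Drop references below the minimum genome span.

    The default of 94 kb is the median plastid genome size of protists;
    excluding smaller outliers keeps reduced or degenerate plastid
    genomes from dragging the model toward under-annotated references.
    """
    missing = [p.genome_id for p in profiles if p.genome_id not in spans]
    if missing:
        raise ValueError(f"no span recorded for reference genomes: {missing}")
    return [p for p in profiles if spans[p.genome_id] >= min_span_bp]


def synthesize_reference_profiles(
    n_genomes: int,
    role: str,
    catalog: Sequence[ModuleDefinition],
    seed: int = 0,
    *,
    plastid_ko_presence: float = 0.95,
    plastid_span_range: tuple[int, int] = (100_000, 250_000),
    mito_pool_fraction: float = 0.05,
    mito_span_range: tuple[int, int] = (15_000, 70_000),
) -> list[tuple[KOProfile, int]]:
    """Generate artificial organelle reference profiles with spans.

    ``plastid_like`` genomes carry most of the catalog's KOs (Bernoulli
    inclusion at ``plastid_ko_presence`` per KO, 1 + Poisson(1) copies)
    — a stand-in for a complete plastid genome whose annotation covers
    nearly the whole module space.  ``mito_like`` genomes draw a handful
    of tokens from a small fixed subpool of the catalog's KOs (the
    numerically smallest ``mito_pool_fraction`` of them), emulating the
    sparse module coverage of a mitochondrial genome.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if role not in ("plastid_like", "mito_like"):
        raise ValueError(f"unknown role {role!r}")
    all_kos = sorted({ko for m in catalog for ko in m.kos})
    out: list[tuple[KOProfile, int]] = []
    for g in range(n_genomes):
        rng = np.random.default_rng(derive_seed(seed, role, g))
        gid = f"{role}_{g:04d}"
        if role == "plastid_like":
            present = [ko for ko in all_kos if rng.random() < plastid_ko_presence]
            counts = {ko: 1 + int(rng.poisson(1.0)) for ko in present}
            span = int(rng.integers(*plastid_span_range, endpoint=True))
        else:
            pool_size = max(2, int(mito_pool_fraction * len(all_kos)))
            pool = all_kos[:pool_size]
            n_tokens = int(rng.integers(pool_size, 3 * pool_size, endpoint=True))
            draws = rng.choice(pool, size=n_tokens, replace=True)
            counts = pd.Series(draws).value_counts().to_dict()
            span = int(rng.integers(*mito_span_range, endpoint=True))
        out.append((KOProfile(gid, counts), span))
    return out


# --- serialization --------------------------------------------------------

def save_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a labeled dataset as TSV with a provenance header line."""
    path = Path(path)
    order = dataset.module_order
    with open(path, "w") as fh:
        fh.write(f"# provenance: {sorted(dataset.provenance.items())!r}\n")
        fh.write("genome_id\texpected_completeness\t" + "\t".join(order) + "\n")
        for ex in dataset.examples:
            vals = "\t".join(f"{v:.10g}" for v in ex.features.values)
            fh.write(f"{ex.source_genome_id}\t{ex.expected_completeness:.10g}\t{vals}\n")


def load_dataset(path: str | Path) -> LabeledDataset:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        provenance = {}
        if first.startswith("#"):
            header = fh.readline()
        else:
            header = first
        cols = header.rstrip("\n").split("\t")
        order = tuple(cols[2:])
        examples = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            vec = ModuleCoverageVector(
                parts[0], order, tuple(float(v) for v in parts[2:])
            )
            examples.append(LabeledExample(parts[0], float(parts[1]), vec))
    return LabeledDataset(examples, provenance)
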