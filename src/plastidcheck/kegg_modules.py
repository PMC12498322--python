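"""KEGG module definitions and module-coverage feature vectors.

A KEGG module DEFINITION string encodes a functional unit as an ordered
series of *steps* separated by spaces.  Within a step, commas list
alternative orthologs (OR), ``+`` joins subunits of a complex (AND) and a
leading ``-`` marks a non-essential component that never counts against
completeness.  Parentheses group sub-expressions; inside parentheses a
space again means AND.

Module completeness of a genome is the fraction of steps whose boolean
expression is satisfied by the genome's set of KO (KEGG Orthology)
identifiers.  Presence is binary: a KO annotated once satisfies a leaf
exactly as well as a KO annotated twenty times.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "KOProfile",
    "ModuleDefinition",
    "ModuleCoverageVector",
    "ModuleParseError",
    "CatalogError",
    "parse_module_definition",
    "module_completeness",
    "coverage_vector",
    "coverage_matrix",
    "load_ko_annotations",
    "load_module_catalog",
]

_KO_RE = re.compile(r"K\d{5}")


class ModuleParseError(ValueError):
    """Raised for malformed module DEFINITION strings; carries position info."""


class CatalogError(ValueError):
    """Raised for an inconsistent module catalog (e.g. duplicate ids)."""


@dataclass(frozen=True)
class KOProfile:
    """A genome's (or bin's) multiset of KO annotations.

    ``counts`` maps K-numbers to positive annotation counts; zero-count
    keys are dropped at construction so the stored mapping is minimal.
    """

    genome_id: str
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for ko, c in self.counts.items():
            c = int(c)
            if c < 0:
                raise ValueError(f"negative count for {ko} in {self.genome_id}")
            if c > 0:
                cleaned[ko] = c
        object.__setattr__(self, "counts", cleaned)

    @property
    def total(self) -> int:
        """Total number of annotation tokens (sum of counts)."""
        return sum(self.counts.values())

    @property
    def present_kos(self) -> frozenset[str]:
        return frozenset(self.counts)

    def tokens(self) -> list[str]:
        """The multiset expanded to one token per annotation, sorted."""
        out: list[str] = []
        for ko in sorted(self.counts):
            out.extend([ko] * self.counts[ko])
        return out


# --- expression tree ------------------------------------------------------

@dataclass(frozen=True)
class Leaf:
    ko: str

    def evaluate(self, present: frozenset[str], optional: frozenset[str]) -> bool:
        return self.ko in optional or self.ko in present

    def canonical(self) -> str:
        return self.ko

    def leaves(self) -> Iterable[str]:
        yield self.ko


@dataclass(frozen=True)
class Node:
    kind: str  # "any" (OR) | "all" (AND)
    children: tuple["Leaf | Node", ...]

    def evaluate(self, present: frozenset[str], optional: frozenset[str]) -> bool:
        results = (c.evaluate(present, optional) for c in self.children)
        return any(results) if self.kind == "any" else all(results)

    def canonical(self) -> str:
        inner = ",".join(c.canonical() for c in self.children) if self.kind == "any" \
            else "+".join(c.canonical() for c in self.children)
        return f"({inner})"

    def leaves(self) -> Iterable[str]:
        for c in self.children:
            yield from c.leaves()


Expr = Leaf | Node


@dataclass(frozen=True)
class ModuleDefinition:
    """A parsed module: ordered steps of boolean expressions over KOs."""

    module_id: str
    steps: tuple[Expr, ...]
    optional_leaves: frozenset[str] = frozenset()

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def kos(self) -> frozenset[str]:
        """All distinct KOs referenced, optional ones included."""
        out: set[str] = set()
        for s in self.steps:
            out.update(s.leaves())
        return frozenset(out)

    def _canon(self, expr: Expr) -> str:
        if isinstance(expr, Leaf):
            return expr.ko
        if expr.kind == "any":
            return "(" + ",".join(self._canon(c) for c in expr.children) + ")"
        # AND: re-emit '-' for fully-optional members so optionality
        # survives the round trip
        parts = []
        for i, c in enumerate(expr.children):
            text = self._canon(c)
            leaves = set(c.leaves())
            optional = bool(leaves) and leaves <= self.optional_leaves
            if i == 0:
                parts.append(("-" if optional else "") + text)
            else:
                parts.append(("-" if optional else "+") + text)
        return "(" + "".join(parts) + ")"

    def canonical(self) -> str:
        return " ".join(self._canon(s) for s in self.steps)


@dataclass(frozen=True)
class ModuleCoverageVector:
    """Fixed-order vector of per-module completeness fractions."""

    genome_id: str
    module_order: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.module_order):
            raise ValueError("values and module_order length mismatch")
        if any(not (0.0 <= v <= 1.0) for v in self.values):
            raise ValueError("coverage values must lie in [0, 1]")


# --- parser ---------------------------------------------------------------

_TOKEN_RE = re.compile(r"K\d{5}|[(),+\-]|\s+|--|.")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    for m in _TOKEN_RE.finditer(text):
        tok = m.group()
        if tok.isspace():
            tokens.append((" ", m.start()))
        else:
            tokens.append((tok, m.start()))
    # collapse runs of spaces
    out: list[tuple[str, int]] = []
    for tok, pos in tokens:
        if tok == " " and out and out[-1][0] == " ":
            continue
        out.append((tok, pos))
    return out


class _Parser:
    """Recursive-descent parser for the DEFINITION grammar.

    Precedence (loosest to tightest): space (AND between steps/terms),
    comma (OR), plus/minus (complex membership / optionality).
    """

    def __init__(self, text: str):
        self.text = text
        self.toks = _tokenize(text.strip())
        self.i = 0
        self.optional: set[str] = set()

    def _peek(self) -> str | None:
        return self.toks[self.i][0] if self.i < len(self.toks) else None

    def _pos(self) -> int:
        return self.toks[self.i][1] if self.i < len(self.toks) else len(self.text)

    def _next(self) -> str:
        tok = self.toks[self.i][0]
        self.i += 1
        return tok

    def _fail(self, msg: str) -> None:
        raise ModuleParseError(f"{msg} at position {self._pos()} in {self.text!r}")

    def parse_steps(self) -> list[Expr]:
        steps = [self.parse_term()]
        while self._peek() == " ":
            self._next()
            if self._peek() is None:
                break
            steps.append(self.parse_term())
        if self._peek() is not None:
            self._fail(f"unexpected {self._peek()!r}")
        return steps

    def parse_space_list(self) -> Expr:
        # inside parentheses a space means AND
        terms = [self.parse_term()]
        while self._peek() == " ":
            self._next()
            terms.append(self.parse_term())
        return terms[0] if len(terms) == 1 else Node("all", tuple(terms))

    def parse_term(self) -> Expr:
        alts = [self.parse_complex()]
        while self._peek() == ",":
            self._next()
            alts.append(self.parse_complex())
        return alts[0] if len(alts) == 1 else Node("any", tuple(alts))

    def parse_complex(self) -> Expr:
        parts: list[Expr] = []
        if self._peek() == "-":  # leading optional member
            self._next()
            unit = self.parse_unit()
            self.optional.update(unit.leaves())
            parts.append(unit)
        else:
            parts.append(self.parse_unit())
        while self._peek() in ("+", "-"):
            op = self._next()
            unit = self.parse_unit()
            if op == "-":
                self.optional.update(unit.leaves())
            parts.append(unit)
        return parts[0] if len(parts) == 1 else Node("all", tuple(parts))

    def parse_unit(self) -> Expr:
        tok = self._peek()
        if tok == "(":
            self._next()
            inner = self.parse_space_list()
            if self._peek() != ")":
                self._fail("unbalanced '(' — expected ')'")
            self._next()
            return inner
        if tok is not None and _KO_RE.fullmatch(tok):
            self._next()
            return Leaf(tok)
        self._fail(f"expected KO identifier or '(', found {tok!r}")
        raise AssertionError  # unreachable


def parse_module_definition(module_id: str, definition_text: str) -> ModuleDefinition:
    """Parse a KEGG DEFINITION string into a :class:`ModuleDefinition`.

    Raises :class:`ModuleParseError` naming the offending position for
    malformed input (unbalanced parentheses, empty definition, stray
    tokens).
    """
    if not definition_text or not definition_text.strip():
        raise ModuleParseError(f"empty definition for module {module_id}")
    parser = _Parser(definition_text)
    steps = parser.parse_steps()
    return ModuleDefinition(
        module_id=module_id,
        steps=tuple(steps),
        optional_leaves=frozenset(parser.optional),
    )


# --- evaluation -----------------------------------------------------------

def module_completeness(definition: ModuleDefinition, present_kos: Iterable[str]) -> float:
    """Fraction of the module's steps satisfied by ``present_kos``.

    A step is satisfied when its boolean expression evaluates true under
    "leaf true iff KO present"; optional leaves are treated as present.
    """
    present = frozenset(present_kos)
    opt = definition.optional_leaves
    satisfied = sum(1 for s in definition.steps if s.evaluate(present, opt))
    return satisfied / len(definition.steps)


def coverage_vector(
    profile: KOProfile,
    catalog: Sequence[ModuleDefinition],
    binary: bool = False,
) -> ModuleCoverageVector:
    """Featurize a profile as per-module completeness in catalog order.

    With ``binary=True`` each value is 1.0 only for fully complete
    modules, mirroring a presence/absence reading of module coverage.
    """
    if not catalog:
        raise CatalogError("module catalog is empty")
    ids = [m.module_id for m in catalog]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CatalogError(f"duplicate module ids in catalog: {dupes}")
    present = profile.present_kos
    vals = []
    for m in catalog:
        v = module_completeness(m, present)
        if binary:
            v = 1.0 if v == 1.0 else 0.0
        vals.append(v)
    return ModuleCoverageVector(profile.genome_id, tuple(ids), tuple(vals))


def coverage_matrix(
    profiles: Sequence[KOProfile],
    catalog: Sequence[ModuleDefinition],
    binary: bool = False,
) -> pd.DataFrame:
    """Stack coverage vectors into a genomes × modules DataFrame."""
    vecs = [coverage_vector(p, catalog, binary=binary) for p in profiles]
    return pd.DataFrame(
        [list(v.values) for v in vecs],
        index=[v.genome_id for v in vecs],
        columns=[m.module_id for m in catalog],
    )


# --- IO -------------------------------------------------------------------

_ANNOTATION_COLUMNS = ("genome_id", "gene_id", "ko_id")


def load_ko_annotations(path: str | Path) -> list[KOProfile]:
    """Read a per-gene KO annotation table into one profile per genome.

    The table is TSV with a header and at least the columns
    ``genome_id``, ``gene_id``, ``ko_id``; rows with an empty ``ko_id``
    (unannotated genes) are ignored and duplicate KOs aggregate into
    counts.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"annotation table {path} is missing required columns: {missing}"
        )
    profiles = []
    for gid, sub in df.groupby("genome_id", sort=True):
        kos = sub.loc[sub["ko_id"] != "", "ko_id"]
        profiles.append(KOProfile(str(gid), kos.value_counts().to_dict()))
    return profiles


def write_ko_annotations(profiles: Sequence[KOProfile], path: str | Path) -> None:
    """Serialize profiles in the annotation-table dialect (round-trips)."""
    rows = []
    for p in profiles:
        i = 0
        for ko in p.tokens():
            rows.append((p.genome_id, f"{p.genome_id}_gene{i:05d}", ko))
            i += 1
        if p.total == 0:
            rows.append((p.genome_id, f"{p.genome_id}_gene00000", ""))
    pd.DataFrame(rows, columns=list(_ANNOTATION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def load_module_catalog(path: str | Path) -> list[ModuleDefinition]:
    """Load a module catalog from a two-column TSV or a directory.

    TSV form: header ``module_id<TAB>definition``; directory form: one
    text file per module (stem = module id, content = DEFINITION string).
    """
    path = Path(path)
    entries: list[tuple[str, str]] = []
    if path.is_dir():
        for f in sorted(path.iterdir()):
            if f.is_file():
                entries.append((f.stem, f.read_text().strip()))
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if df.shape[1] < 2:
            raise CatalogError(f"catalog {path} must have two columns")
        for _, row in df.iterrows():
            entries.append((str(row.iloc[0]), str(row.iloc[1])))
    ids = [e[0] for e in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CatalogError(f"duplicate module ids in catalog: {dupes}")
    return [parse_module_definition(mid, text) for mid, text in entries]
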