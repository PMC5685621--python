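"""Readers and writers for the standard formats the toolkit touches.

Dialects are deliberately strict and small:

* FASTA: DNA only; lowercase is folded to uppercase; any character outside
  ``{A, C, G, T}`` becomes ``N`` (ambiguity codes are never treated as
  literal matches downstream).
* PHYLIP distance matrices: square (not triangular).  The default
  ``relaxed`` dialect is tab separated with unrestricted names; the
  ``strict`` dialect pads names to 10 characters, as classic NEIGHBOR
  expects.
* Newick: branch lengths, internal labels, quoted labels and
  multifurcations are supported (delegated to scikit-bio).
* Taxonomy / abundance / metadata: headerless or headered TSV as
  documented on each reader.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

__all__ = [
    "SequenceRecord",
    "SequenceSet",
    "DistanceMatrix",
    "AbundanceTable",
    "read_fasta",
    "write_fasta",
    "read_phylip_distances",
    "write_phylip_distances",
    "read_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
    "read_taxonomy",
    "read_abundance",
    "read_metadata",
]

_VALID = set("ACGT")
_WS = re.compile(r"\s+")


def _normalize_seq(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in _VALID else "N" for c in seq)


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet ``{A, C, G, T, N}``."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        object.__setattr__(self, "id", _WS.sub("_", self.id.strip()))
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - (_VALID | {"N"})
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


class SequenceSet:
    """Ordered collection of :class:`SequenceRecord` with unique ids."""

    def __init__(self, records):
        self.records = list(records)
        self._by_id = {}
        for r in self.records:
            if r.id in self._by_id:
                raise ValueError(f"duplicate sequence id {r.id!r}")
            self._by_id[r.id] = r

    @property
    def ids(self):
        return [r.id for r in self.records]

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, int):
            return self.records[key]
        return self._by_id[key]

    def __contains__(self, key):
        return key in self._by_id


class DistanceMatrix:
    """Symmetric labelled matrix of pairwise dissimilarities.

    Construction enforces the invariants: square, finite, non-negative,
    symmetric within ``sym_tol`` (then symmetrized exactly) and zero on
    the diagonal within the same tolerance.
    """

    #: tolerance used when checking symmetry / diagonal on construction
    sym_tol = 1e-9

    def __init__(self, values, labels):
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(labels) != values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in distance matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("distance matrix has non-finite entries")
        if np.max(np.abs(values - values.T)) > self.sym_tol:
            raise ValueError("distance matrix is not symmetric within 1e-9")
        if np.max(np.abs(np.diag(values))) > self.sym_tol:
            raise ValueError("distance matrix diagonal is not zero")
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        # tiny numeric negatives are clamped; genuine negatives are errors
        if values.min() < -self.sym_tol:
            raise ValueError("distance matrix has negative entries")
        np.clip(values, 0.0, None, out=values)
        self.values = values
        self.labels = tuple(labels)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self):
        return len(self.labels)

    def between(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def reorder(self, labels) -> "DistanceMatrix":
        idx = [self._index[l] for l in labels]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class AbundanceTable:
    """Sample-by-OTU table of non-negative real abundances."""

    sample_ids: tuple
    otu_ids: tuple
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.otu_ids = tuple(str(o) for o in self.otu_ids)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError("counts shape does not match ids")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("abundances must be finite and non-negative")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError("every sample needs at least one positive entry")

    def sample_vector(self, sample_id: str) -> dict:
        i = self.sample_ids.index(sample_id)
        return dict(zip(self.otu_ids, self.counts[i]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> SequenceSet:
    """Read a multi-FASTA file into a :class:`SequenceSet`.

    Lowercase is folded to uppercase; characters outside ``ACGT`` become
    ``N``.  Duplicate ids and empty files are errors.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, _normalize_seq(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in seqs:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices
# ---------------------------------------------------------------------------

def write_phylip_distances(dm: DistanceMatrix, path, dialect: str = "relaxed") -> None:
    """Write a square PHYLIP distance matrix.

    ``relaxed`` (default) uses tab separation and unrestricted names;
    ``strict`` pads names to 10 characters and rejects longer ones.
    """
    if dialect not in ("relaxed", "strict"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for i, lab in enumerate(dm.labels):
            row = ["%.10g" % v for v in dm.values[i]]
            if dialect == "strict":
                if len(lab) > 10:
                    raise ValueError(
                        f"name {lab!r} exceeds 10 characters (strict PHYLIP dialect)"
                    )
                fh.write(lab.ljust(10) + "  " + "  ".join(row) + "\n")
            else:
                fh.write(lab + "\t" + "\t".join(row) + "\n")


def read_phylip_distances(path, dialect: str = "relaxed") -> DistanceMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty PHYLIP file {path}")
    n = int(lines[0].split()[0])
    if len(lines) - 1 != n:
        raise ValueError(f"expected {n} rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        if dialect == "strict":
            name, rest = ln[:10].strip(), ln[10:]
            vals = [float(x) for x in rest.split()]
        else:
            parts = ln.split("\t") if "\t" in ln else ln.split()
            name, vals = parts[0], [float(x) for x in parts[1:]]
        if len(vals) != n:
            raise ValueError(f"row {name!r} has {len(vals)} values, expected {n}")
        labels.append(name)
        rows.append(vals)
    return DistanceMatrix(np.array(rows), labels)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(text: str) -> TreeNode:
    """Parse a Newick string into a tree, checking leaf-label uniqueness."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in newick string")
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick", convert_underscores=False)
    except Exception as exc:  # skbio raises its own parse errors
        raise ValueError(f"invalid newick: {exc}") from exc
    names = [t.name for t in tree.tips()]
    if any(n is None or n == "" for n in names):
        raise ValueError("newick tree has unnamed leaves")
    dup = {n for n in names if names.count(n) > 1}
    if dup:
        raise ValueError(f"duplicate leaf labels: {sorted(dup)}")
    return tree


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick_file(path) -> TreeNode:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick_file(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_taxonomy(path):
    """Read a headerless two-column TSV of ``sequence_id<TAB>rank string``.

    Rank strings are semicolon separated ("k__Bacteria; p__Firmicutes;
    ...").  Prefixes are kept verbatim; empty rank slots are recorded as
    empty strings; rank depth is positional.
    """
    from .taxonomy import TaxonomyTable  # local import avoids a module cycle

    assignments = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated fields")
            sid = _WS.sub("_", parts[0].strip())
            if sid in assignments:
                raise ValueError(f"duplicate sequence id {sid!r}")
            ranks = tuple(r.strip() for r in parts[1].split(";"))
            assignments[sid] = ranks
    if not assignments:
        raise ValueError(f"no taxonomy rows found in {path}")
    return TaxonomyTable(assignments)


def read_abundance(path) -> AbundanceTable:
    """Read a sample-by-OTU TSV: header row of OTU ids, first column sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative abundance values")
    return AbundanceTable(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), counts)


def write_abundance(table: AbundanceTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t")


def read_metadata(path) -> dict:
    """Read a sample metadata TSV (header row; first column = sample id).

    Returns ``{sample_id: {column: value}}``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return {str(idx): row.to_dict() for idx, row in df.iterrows()}
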