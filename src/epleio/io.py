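"""Readers and writers for alignments, trees and estimation reports.

Alignments are accepted in CLUSTAL or FASTA; trees as Newick (the payload of
a Phylip-style tree file).  Residues outside the 20 canonical amino acids are
either treated as missing data (gap ``-`` and the ambiguity codes ``X``,
``B``, ``Z``) or rejected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import AlignIO

from .errors import InputError, ParseError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: symbols accepted in input but carrying no state information
MISSING_SYMBOLS = frozenset("-XBZ")
_ALLOWED = frozenset(AMINO_ACIDS) | MISSING_SYMBOLS

MIN_TAXA = 4


def is_missing(symbol: str) -> bool:
    """True for gap or ambiguity symbols that carry no residue state."""
    return symbol in MISSING_SYMBOLS


@dataclass
class Alignment:
    """A protein multiple sequence alignment.

    Parameters
    ----------
    taxa
        Ordered, unique, non-empty taxon labels.
    data
        ``(n_taxa, n_sites)`` array of single uppercase characters; each is a
        canonical amino acid or one of the missing symbols.
    source_format
        ``"clustal"`` or ``"fasta"``.
    """

    taxa: list[str]
    data: np.ndarray
    source_format: str = "fasta"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise InputError("alignment matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise InputError(f"duplicate taxon labels: {dupes}")
        if any(not t for t in self.taxa):
            raise InputError("empty taxon label")
        if self.n_taxa < MIN_TAXA:
            raise InputError(
                f"at least {MIN_TAXA} sequences required, got {self.n_taxa}"
            )
        if self.n_taxa == MIN_TAXA:
            logger.warning(
                "alignment has exactly %d sequences; estimates from the "
                "minimum number of taxa can be unstable", MIN_TAXA,
            )
        bad = ~np.isin(self.data, list(_ALLOWED))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ParseError(
                f"unknown residue symbol {self.data[i, j]!r} in sequence "
                f"{self.taxa[i]!r} at column {j + 1}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(self.data[self.taxa.index(taxon)])

    def column_states(self, j: int) -> dict[str, str | None]:
        """Map taxon -> residue at column ``j``, with missing mapped to None."""
        col = self.data[:, j]
        return {
            t: (None if is_missing(s) else s) for t, s in zip(self.taxa, col)
        }


def _sniff_format(path: str | Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "clustal" if line.upper().startswith("CLUSTAL") else "fasta"
    raise ParseError(f"{path}: empty file")


def read_alignment(path: str | Path, format: str = "auto") -> Alignment:
    """Read a protein alignment from a CLUSTAL or FASTA file.

    ``format="auto"`` sniffs the CLUSTAL header line.  Sequence order is
    preserved; labels must be unique; at least four sequences are required.
    """
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("clustal", "fasta"):
        raise InputError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        msg = str(exc)
        if "same length" in msg.lower():
            raise InputError(
                f"{path}: sequences have unequal lengths (not aligned)"
            ) from exc
        raise ParseError(f"{path}: cannot parse as {format}: {msg}") from exc
    taxa = [rec.id for rec in msa]
    data = np.array([list(str(rec.seq).upper()) for rec in msa], dtype="<U1")
    return Alignment(taxa=taxa, data=data, source_format=format)


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read one Newick tree; missing branch lengths default to 0 (warned)."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error classes
        if "Duplicate taxon labels" in str(exc):
            raise InputError(f"{path}: duplicate leaf labels") from exc
        raise ParseError(f"{path}: malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(not lab for lab in labels):
        raise InputError(f"{path}: empty leaf label")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise InputError(f"{path}: duplicate leaf labels: {dupes}")
    n_missing = sum(1 for e in tree.preorder_edge_iter() if e.length is None)
    if n_missing:
        # the root edge legitimately has no length; only warn beyond that
        if n_missing > 1:
            logger.warning(
                "%s: %d branches without length; defaulting to 0",
                path, n_missing - 1,
            )
        for e in tree.preorder_edge_iter():
            if e.length is None:
                e.length = 0.0
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


@dataclass
class EstimateReport:
    """Complete result of one estimation run, including provenance."""

    ke: float
    var_ke: float
    g: float
    se: float
    be: float
    h: float
    var_h: float
    m: float
    v: float
    dn: float
    ds: float
    var_dn: float
    var_ds: float
    ratio: float
    correction_mode: str
    correction_factor: float
    tree_length: float
    n_sites_used: int
    n_excluded: int
    n_taxa: int
    tree_source: str
    n_boot: int
    seed: int
    aln_path: str = ""
    tree_path: str = ""
    be_formula: str = "reconstructed-stabilizing-selection"
    distance_model: str = "poisson-corrected-p"
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EstimateReport":
        return cls(**d)


_REPORT_FIELDS = [f.name for f in dataclasses.fields(EstimateReport)]


def write_report(report: EstimateReport, path: str | Path, format: str = "tsv") -> None:
    """Write a report as a one-row TSV or as JSON; both round-trip."""
    d = report.to_dict()
    if format == "json":
        Path(path).write_text(json.dumps(d, indent=2) + "\n")
    elif format == "tsv":
        row = [
            ";".join(d[k]) if k == "warnings" else repr(d[k])
            if isinstance(d[k], float) else str(d[k])
            for k in _REPORT_FIELDS
        ]
        Path(path).write_text(
            "\t".join(_REPORT_FIELDS) + "\n" + "\t".join(row) + "\n"
        )
    else:
        raise InputError(f"unsupported report format {format!r}")


def read_report(path: str | Path, format: str = "json") -> EstimateReport:
    if format == "json":
        return EstimateReport.from_dict(json.loads(Path(path).read_text()))
    if format == "tsv":
        header, row = Path(path).read_text().splitlines()[:2]
        d: dict = dict(zip(header.split("\t"), row.split("\t")))
        for f in dataclasses.fields(EstimateReport):
            if f.name == "warnings":
                d[f.name] = [w for w in d[f.name].split(";") if w]
            elif f.type in ("float", float):
                d[f.name] = float(d[f.name])
            elif f.type in ("int", int):
                d[f.name] = int(d[f.name])
        return EstimateReport.from_dict(d)
    raise InputError(f"unsupported report format {format!r}")
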