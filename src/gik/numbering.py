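"""Generic residue numbering: Ballesteros-Weinstein (class A GPCRs) and CGN (Galpha).

Receptor positions are written ``helix.index`` (``3.54``, with the ``34.5x``
convention for ICL2); Galpha positions follow the common Galpha numbering
(CGN) ``segment.index`` (``H5.20``, ``S3.01``).  CGN strings are accepted
with or without the formal ``G.`` prefix and always emitted in the short
form.

Annotation transfers labels from a packaged reference table onto a chain by
global sequence alignment (BLOSUM62, affine gaps), never across gap columns.
The packaged tables are synthetic sequence scaffolds: the residue-number to
generic-label anchoring follows the published conventions for CB1, Galpha-s
and Galpha-i1, but the connecting sequence is generated, so they support the
synthetic pipeline and offline determinism rather than annotation of
arbitrary real structures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils import seq1

from .errors import AlignmentError, MappingError, ParameterError
from .structure_io import AtomRecord, ResidueKey, Structure

_BW_SEGMENTS = {
    "1": "TM1", "2": "TM2", "3": "TM3", "4": "TM4", "5": "TM5", "6": "TM6",
    "7": "TM7", "8": "H8", "12": "ICL1", "23": "ECL1", "34": "ICL2",
    "45": "ECL2", "56": "ICL3", "67": "ECL3", "78": "TM7-H8",
}
_CGN_RE = re.compile(r"^(?:G\.)?([A-Za-z][A-Za-z0-9]*)\.(\d{2})$")
_BW_RE = re.compile(r"^(\d{1,2})\.(\d{1,2})$")


@dataclass(frozen=True)
class GenericLabel:
    """A generic residue label under one scheme (BW or CGN)."""

    scheme: str  # "BW" | "CGN"
    segment: str
    position: str

    def __str__(self) -> str:
        return self.position

    @staticmethod
    def parse(text: str, scheme: str | None = None) -> "GenericLabel":
        text = text.strip()
        if scheme is None:
            scheme = "BW" if text[:1].isdigit() else "CGN"
        scheme = scheme.upper()
        if scheme == "BW":
            m = _BW_RE.match(text)
            if not m or m.group(1) not in _BW_SEGMENTS:
                raise ParameterError(f"{text!r} is not a valid BW position")
            return GenericLabel("BW", _BW_SEGMENTS[m.group(1)], text)
        if scheme == "CGN":
            m = _CGN_RE.match(text)
            if not m:
                raise ParameterError(f"{text!r} is not a valid CGN position")
            seg, idx = m.group(1), m.group(2)
            return GenericLabel("CGN", seg, f"{seg}.{idx}")
        raise ParameterError(f"unknown scheme {scheme!r}")


def parse_label(text: str, scheme: str | None = None) -> GenericLabel:
    """Shorthand for :meth:`GenericLabel.parse`."""
    return GenericLabel.parse(text, scheme)


class NumberingMap:
    """Bijection between residues of one chain and generic labels."""

    def __init__(self, chain_id: str, pairs, source: str = ""):
        self.chain_id = chain_id
        self.source = source
        self.coverage: float = float("nan")
        self._by_res: dict[tuple[int, str], tuple[ResidueKey, GenericLabel]] = {}
        self._by_pos: dict[str, ResidueKey] = {}
        for key, label in pairs:
            if key.chain_id != chain_id:
                raise MappingError(f"residue {key} is not on chain {chain_id!r}")
            rid = (key.resnum, key.icode)
            if rid in self._by_res:
                raise MappingError(f"residue {key} mapped to two labels")
            if label.position in self._by_pos:
                raise MappingError(f"label {label} mapped to two residues")
            self._by_res[rid] = (key, label)
            self._by_pos[label.position] = key

    def __len__(self) -> int:
        return len(self._by_res)

    def items(self):
        return [(k, lab) for k, lab in self._by_res.values()]

    def labels(self) -> list[GenericLabel]:
        return [lab for _, lab in self._by_res.values()]

    def to_generic(self, key: ResidueKey) -> GenericLabel:
        try:
            return self._by_res[(key.resnum, key.icode)][1]
        except KeyError:
            raise MappingError(f"residue {key} has no generic label") from None

    def to_residue(self, label: GenericLabel | str) -> ResidueKey:
        pos = label.position if isinstance(label, GenericLabel) else _normalize_pos(label)
        try:
            return self._by_pos[pos]
        except KeyError:
            raise MappingError(f"label {pos!r} not mapped on chain {self.chain_id!r}") from None

    def lookup_position(self, pos: str) -> ResidueKey | None:
        """Like :meth:`to_residue` but returns None when unmapped (for selections)."""
        return self._by_pos.get(_normalize_pos(pos))


def _normalize_pos(text: str) -> str:
    text = text.strip()
    return text[2:] if text.upper().startswith("G.") else text


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------

_PACKAGED = {
    "cb1": ("data", "cb1_bw.synthetic.tsv"),
    "gas": ("data", "gnas_cgn.synthetic.tsv"),
    "gnas": ("data", "gnas_cgn.synthetic.tsv"),
    "gai1": ("data", "gnai1_cgn.synthetic.tsv"),
    "gnai1": ("data", "gnai1_cgn.synthetic.tsv"),
}


class ReferenceTable:
    """A reference sequence with anchored generic labels.

    Backed by a DataFrame with columns ``ref_seq_index`` (author numbering of
    the reference), ``ref_aa`` (one-letter), ``generic_label`` (may be empty
    for unlabeled connecting residues) and ``segment``.
    """

    def __init__(self, df: pd.DataFrame, name: str = "", scheme: str | None = None):
        required = {"ref_seq_index", "ref_aa", "generic_label", "segment"}
        if not required.issubset(df.columns):
            raise ParameterError(f"reference table missing columns {required - set(df.columns)}")
        self.df = df.sort_values("ref_seq_index").reset_index(drop=True)
        self.df["generic_label"] = self.df["generic_label"].fillna("")
        self.df["segment"] = self.df["segment"].fillna("")
        self.name = name
        labeled = self.df[self.df.generic_label != ""]
        if scheme is None:
            scheme = "BW" if len(labeled) and labeled.generic_label.iloc[0][0].isdigit() else "CGN"
        self.scheme = scheme

    @property
    def sequence(self) -> str:
        return "".join(self.df.ref_aa)

    def labels(self) -> list[GenericLabel]:
        return [GenericLabel.parse(s, self.scheme)
                for s in self.df.generic_label if s]


def load_reference(name_or_path: str | Path) -> ReferenceTable:
    """Load a packaged reference table by id (cb1, gas, gai1) or a TSV path."""
    key = str(name_or_path).lower()
    if key in _PACKAGED:
        pkg_dir, fname = _PACKAGED[key]
    dtypes = {"ref_aa": str, "generic_label": str, "segment": str}
    if key in _PACKAGED:
        pkg_dir, fname = _PACKAGED[key]
        with resources.files("gik").joinpath(f"{pkg_dir}/{fname}").open("r") as fh:
            df = pd.read_csv(fh, sep="\t", keep_default_na=False, dtype=dtypes)
        return ReferenceTable(df, name=key)
    path = Path(name_or_path)
    if not path.exists():
        raise ParameterError(f"unknown reference {name_or_path!r}")
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=dtypes)
    return ReferenceTable(df, name=path.stem)


def structure_from_reference(table: ReferenceTable, chain_id: str = "A",
                             offset: int = 0, id: str | None = None) -> Structure:
    """A CA-only chain realizing the reference sequence (test/demo helper).

    Residues are laid out on a straight line; ``offset`` shifts the author
    numbering, which annotation must be invariant to.
    """
    aa3 = {v: k for k, v in _AA3_TO_1.items()}
    residues = []
    for i, row in table.df.iterrows():
        key = ResidueKey(chain_id, int(row.ref_seq_index) + offset, "",
                         aa3.get(row.ref_aa, "UNK"))
        atom = AtomRecord("CA", "C", np.array([3.8 * i, 0.0, 0.0]))
        residues.append((key, [atom]))
    return Structure(id or f"ref-{table.name}", residues)


_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def chain_sequence(structure: Structure, chain: str) -> tuple[str, list[ResidueKey]]:
    keys = [k for k in structure.residue_keys() if k.chain_id == chain]
    if not keys:
        raise AlignmentError(f"chain {chain!r} not found in {structure.id!r}")
    seq = "".join(_AA3_TO_1.get(k.resname.upper(), seq1(k.resname, undef_code="X"))
                  for k in keys)
    return seq.upper(), keys


def annotate(structure: Structure, chain: str, reference: ReferenceTable | str,
             min_identity: float = 0.9) -> NumberingMap:
    """Transfer generic labels from a reference table onto one chain.

    Global alignment with BLOSUM62 and affine gaps (open 10, extend 0.5);
    labels cross only aligned (identical or substituted) columns, never gaps.
    Alignment identity below ``min_identity`` raises, on the assumption that
    the chain is not the protein the table describes.  The resulting map
    records the fraction of reference labels that found a residue as
    ``coverage``.
    """
    if isinstance(reference, (str, Path)):
        reference = load_reference(reference)
    seq, keys = chain_sequence(structure, chain)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    ref_seq = reference.sequence
    aln = aligner.align(ref_seq, seq)[0]

    ref_blocks, q_blocks = aln.aligned
    pairs, identical, aligned_cols = [], 0, 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, q_blocks):
        for k in range(re_ - rs):
            ri, qi = rs + k, qs + k
            aligned_cols += 1
            if ref_seq[ri] == seq[qi]:
                identical += 1
            lab = reference.df.generic_label.iloc[ri]
            if lab:
                pairs.append((keys[qi], GenericLabel.parse(lab, reference.scheme)))
    if aligned_cols == 0 or identical / aligned_cols < min_identity:
        ident = identical / aligned_cols if aligned_cols else 0.0
        raise AlignmentError(
            f"chain {chain!r} aligns to reference {reference.name!r} with identity "
            f"{ident:.2f} < {min_identity} - likely the wrong protein")
    nm = NumberingMap(chain, pairs, source=reference.name)
    n_labels = int((reference.df.generic_label != "").sum())
    nm.coverage = len(pairs) / n_labels if n_labels else 0.0
    return nm
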