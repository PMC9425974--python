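"""Column homogeneity of protein alignments against a substitution matrix.

The homogeneity of an alignment column measures how well the best consensus
amino acid explains the observed residues, calibrated against the expected
score of a random residue assortment.  For a column with residues ``a_i`` and
per-sequence weights ``w_i`` (equal, ``1/N``, by default), each candidate
amino acid ``x`` receives the score

    Q_x = sum_i w_i * S(a_i, x)

where ``S`` is a pairwise substitution matrix (BLOSUM62 by default).  The
consensus ``c`` maximizes ``Q_x``; the random-expectation baseline is
``Q_R = sum_b f_b * Q_b`` over background amino-acid frequencies ``f_b``, and

    h = max((Q_c - Q_R) / (S(c, c) - Q_R), 0)

so that an invariant column has ``h = 1`` and a column indistinguishable from
a random assortment has ``h = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "GAP_CHARS",
    "ScoreModel",
    "FamilyAlignment",
    "ColumnView",
    "HomogeneityProfile",
    "load_score_matrix",
    "default_score_model",
    "column_consensus",
    "column_homogeneity",
    "alignment_passes_filter",
    "alignment_homogeneity_profile",
]

#: The 20 standard amino acids in fixed alphabetical order.  This order is the
#: tie-break order for consensus selection.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Characters treated as gaps.  Ambiguous residues (B, Z, X, U, O, J) carry no
#: guaranteed score in every matrix file and are handled like gaps.
GAP_CHARS = frozenset("-.*BZXUOJ bzxuoj")

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Column mask codes
SCORED = "scored"
SKIPPED_SINGULAR = "skipped-singular"
SKIPPED_ALL_GAP = "skipped-all-gap"


class MatrixFormatError(ValueError):
    """Raised when a substitution-matrix file cannot be used."""


class DegenerateColumnError(ValueError):
    """Raised for columns that cannot be scored (e.g. all gaps)."""


@dataclass(frozen=True)
class ScoreModel:
    """Substitution scores plus background amino-acid frequencies.

    Attributes
    ----------
    matrix : (20, 20) ndarray
        Symmetric integer-valued scores indexed by :data:`AMINO_ACIDS`.
    background : (20,) ndarray
        Strictly positive relative frequencies summing to 1.
    metadata : dict
        Provenance of the matrix and the frequency table.
    """

    matrix: np.ndarray
    background: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        f = np.asarray(self.background, dtype=float)
        if m.shape != (20, 20):
            raise MatrixFormatError(f"expected a 20x20 matrix, got {m.shape}")
        if not np.array_equal(m, m.T):
            raise MatrixFormatError("substitution matrix is not symmetric")
        if f.shape != (20,):
            raise MatrixFormatError("background table must have 20 entries")
        if np.any(f <= 0):
            raise MatrixFormatError("background frequencies must be positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise MatrixFormatError("background frequencies must sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", f)

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[_AA_INDEX[a], _AA_INDEX[b]])

    def freq(self, a: str) -> float:
        return float(self.background[_AA_INDEX[a]])


def _matrix_from_biopython(mat) -> np.ndarray:
    alphabet = set(mat.alphabet)
    missing = [aa for aa in AMINO_ACIDS if aa not in alphabet]
    if missing:
        raise MatrixFormatError(f"matrix is missing amino acids: {missing}")
    out = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a, b]
    if not np.array_equal(out, out.T):
        raise MatrixFormatError("substitution matrix is not symmetric")
    return out


def load_background_frequencies(path: str | Path | None = None) -> tuple[np.ndarray, str]:
    """Read a 20-row ``<amino acid>\\t<frequency>`` table; normalize to sum 1.

    Returns the frequency vector (ordered by :data:`AMINO_ACIDS`) and a
    provenance string.  A table that does not sum to 1 (e.g. counts per 1000)
    is rescaled with a warning.
    """
    if path is None:
        source = "builtin:robinson_frequencies"
        text = (
            resources.files("varcog.data")
            .joinpath("robinson_frequencies.tsv")
            .read_text()
        )
    else:
        source = str(path)
        text = Path(path).read_text()
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, val = line.split()
        values[aa.upper()] = float(val)
    missing = [aa for aa in AMINO_ACIDS if aa not in values]
    if missing:
        raise MatrixFormatError(f"frequency table missing amino acids: {missing}")
    f = np.array([values[aa] for aa in AMINO_ACIDS], dtype=float)
    if np.any(f <= 0):
        raise MatrixFormatError("background frequencies must be positive")
    total = f.sum()
    if abs(total - 1.0) > 1e-9:
        if path is not None:  # builtin table is tabulated per 1000 by design
            warnings.warn(
                f"background frequencies sum to {total:g}; renormalizing to 1",
                stacklevel=2,
            )
        f = f / total
    return f, source


def load_score_matrix(
    path: str | Path | None = None,
    freqs_path: str | Path | None = None,
) -> ScoreModel:
    """Load a substitution matrix (NCBI text format) with background frequencies.

    With ``path=None`` the built-in BLOSUM62 matrix is used.  With
    ``freqs_path=None`` the built-in Robinson-Robinson background table is
    used; its identity is recorded in ``metadata``.
    """
    if path is None:
        raw = substitution_matrices.load("BLOSUM62")
        matrix_source = "builtin:BLOSUM62"
    else:
        try:
            raw = substitution_matrices.read(str(path))
        except Exception as exc:  # malformed file
            raise MatrixFormatError(f"cannot parse matrix file {path}: {exc}") from exc
        matrix_source = str(path)
    matrix = _matrix_from_biopython(raw)
    background, freq_source = load_background_frequencies(freqs_path)
    return ScoreModel(
        matrix=matrix,
        background=background,
        metadata={"matrix": matrix_source, "background": freq_source},
    )


def default_score_model() -> ScoreModel:
    """BLOSUM62 with the built-in Robinson-Robinson background table."""
    return load_score_matrix(None, None)


@dataclass
class FamilyAlignment:
    """A gapped protein alignment for one family, with genome labels."""

    family_id: str
    rows: list[tuple[str, str, str]]  # (sequence_id, genome_id, residues)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"alignment {self.family_id!r} has no rows")
        lengths = {len(r[2]) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(
                f"alignment {self.family_id!r} has ragged rows (lengths {sorted(lengths)})"
            )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][2])

    def column(self, j: int) -> list[str]:
        return [r[2][j].upper() for r in self.rows]

    @property
    def genomes(self) -> set[str]:
        return {r[1] for r in self.rows}


@dataclass
class ColumnView:
    """One alignment column: residues (or gaps) with per-sequence weights."""

    residues: Sequence[str]
    weights: Sequence[float]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.residues):
            raise ValueError("weights and residues differ in length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        self.weights = w


@dataclass
class HomogeneityProfile:
    """Per-column homogeneity values with a scored/skipped mask."""

    family_id: str
    h: np.ndarray  # per-column; NaN where masked
    column_mask: list[str]  # SCORED | SKIPPED_SINGULAR | SKIPPED_ALL_GAP

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if len(self.h) != len(self.column_mask):
            raise ValueError("h and column_mask differ in length")

    @property
    def scored(self) -> np.ndarray:
        """Homogeneity values of scored columns only."""
        return self.h[[m == SCORED for m in self.column_mask]]

    @property
    def scored_indices(self) -> np.ndarray:
        return np.flatnonzero([m == SCORED for m in self.column_mask])

    @property
    def mean_h(self) -> float:
        vals = self.scored
        if vals.size == 0:
            raise ValueError(f"profile {self.family_id!r} has no scored columns")
        return float(vals.mean())


def _nongap_weights(col: ColumnView) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate non-gap residues into per-amino-acid weights summing to 1."""
    agg = np.zeros(20)
    for res, w in zip(col.residues, col.weights):
        aa = res.upper()
        if aa in _AA_INDEX:
            agg[_AA_INDEX[aa]] += w
    total = agg.sum()
    if total <= 0:
        raise DegenerateColumnError("column contains no standard residues")
    return agg / total, agg


def _q_vector(col: ColumnView, model: ScoreModel) -> np.ndarray:
    """Q_x for all 20 candidate amino acids, with gap-renormalized weights."""
    weights, _ = _nongap_weights(col)
    return weights @ model.matrix


#: Absolute tolerance for consensus-score ties.  Real Q differences are
#: multiples of the weight resolution times integer score steps, far above
#: this; it only absorbs floating-point summation-order noise on exact ties.
_TIE_TOL = 1e-9


def _argmax_alphabetical(q: np.ndarray) -> int:
    """First index (alphabetical order) whose Q is within tolerance of the max."""
    return int(np.flatnonzero(q >= q.max() - _TIE_TOL)[0])


def column_consensus(col: ColumnView, model: ScoreModel) -> tuple[str, float]:
    """Effective consensus amino acid ``c = argmax_x Q_x`` and its score ``Q_c``.

    Ties are broken by the fixed alphabetical order of :data:`AMINO_ACIDS`.
    """
    q = _q_vector(col, model)
    idx = _argmax_alphabetical(q)
    return AMINO_ACIDS[idx], float(q[idx])


def column_homogeneity(col: ColumnView, model: ScoreModel) -> float:
    """Homogeneity ``h = max((Q_c - Q_R)/(S_cc - Q_R), 0)`` of one column."""
    q = _q_vector(col, model)
    idx = _argmax_alphabetical(q)
    q_c = q[idx]
    q_r = float(model.background @ q)
    s_cc = model.matrix[idx, idx]
    denom = s_cc - q_r
    if abs(denom) < 1e-12:
        raise DegenerateColumnError(
            "degenerate denominator: consensus self-score equals random expectation"
        )
    return max(float((q_c - q_r) / denom), 0.0)


def _nongap_row_indices(aln: FamilyAlignment, j: int) -> list[int]:
    return [
        i for i, (_, _, res) in enumerate(aln.rows) if res[j].upper() in _AA_INDEX
    ]


def alignment_passes_filter(
    aln: FamilyAlignment,
    min_sequences: int = 8,
    min_columns: int = 60,
) -> tuple[bool, int, int]:
    """Apply the family inclusion filter.

    A family qualifies with at least ``min_sequences`` non-identical sequences
    (exact duplicates of the ungapped residue string removed) and at least
    ``min_columns`` informative columns.  A column is informative if its
    non-gap residues come from two or more sequences; columns whose residues
    come from exactly one sequence ("singular insertions") and all-gap columns
    are excluded.

    Returns ``(passes, n_nonidentical, n_informative_columns)``.
    """
    ungapped = {
        "".join(c for c in res.upper() if c in _AA_INDEX) for _, _, res in aln.rows
    }
    n_nonidentical = len(ungapped)
    n_informative = sum(
        1 for j in range(aln.n_columns) if len(_nongap_row_indices(aln, j)) >= 2
    )
    return (
        n_nonidentical >= min_sequences and n_informative >= min_columns,
        n_nonidentical,
        n_informative,
    )


def alignment_homogeneity_profile(
    aln: FamilyAlignment,
    model: ScoreModel,
    weights: Sequence[float] | None = None,
    require_filter: bool = True,
) -> HomogeneityProfile:
    """Per-column homogeneity for a whole alignment.

    Sequences get equal weights ``1/N`` unless an explicit weight vector
    (summing to 1) is supplied.  Columns with fewer than two non-gap residues
    are masked: zero residues as all-gap, one as a singular insertion.  Unless
    ``require_filter=False``, the alignment must pass
    :func:`alignment_passes_filter`.
    """
    if weights is None:
        w = np.full(aln.n_rows, 1.0 / aln.n_rows)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != aln.n_rows:
            raise ValueError("weight vector length does not match alignment")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
    if require_filter:
        ok, n_seq, n_col = alignment_passes_filter(aln)
        if not ok:
            raise ValueError(
                f"alignment {aln.family_id!r} fails the inclusion filter "
                f"({n_seq} non-identical sequences, {n_col} informative columns); "
                "pass require_filter=False to override"
            )
    h = np.full(aln.n_columns, np.nan)
    mask: list[str] = []
    for j in range(aln.n_columns):
        nongap = _nongap_row_indices(aln, j)
        if len(nongap) == 0:
            mask.append(SKIPPED_ALL_GAP)
        elif len(nongap) == 1:
            mask.append(SKIPPED_SINGULAR)
        else:
            col = ColumnView(residues=aln.column(j), weights=w)
            h[j] = column_homogeneity(col, model)
            mask.append(SCORED)
    return HomogeneityProfile(family_id=aln.family_id, h=h, column_mask=mask)
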