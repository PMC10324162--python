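"""Score-matrix construction: interaction scores and within-domain similarities.

Three score matrices enter the embedding loss: cross-domain interaction
scores (0.9 for observed interactions, missing otherwise), drug-drug chemical
similarities (Jaccard over substructure sets), and target-target genomic
similarities (normalized Smith-Waterman).  Precomputed similarity matrices
are accepted as-is; the Jaccard/SW routines exist so raw inputs and synthetic
fixtures work without external chemistry toolkits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SubstructureSet",
    "SwParams",
    "ScoreSet",
    "DEFAULT_INTERACTION_SCORE",
    "build_interaction_scores",
    "jaccard_similarity",
    "smith_waterman",
    "normalized_sw",
    "dataset_sparsity",
    "validate_similarity_matrix",
]

#: Score assigned to observed interacting pairs; non-interacting pairs stay NA.
DEFAULT_INTERACTION_SCORE = 0.9


@dataclass(frozen=True)
class SubstructureSet:
    """A drug's chemical substructures as a finite set of discrete tokens."""

    drug_id: str
    substructures: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "substructures", frozenset(self.substructures))


@dataclass(frozen=True)
class SwParams:
    """Local-alignment scoring parameters.

    Gap cost convention: the first residue of a gap costs ``gap_open``, each
    further residue ``gap_extend``; with ``gap_extend == gap_open`` the
    penalty is linear in gap length.  ``substitution`` maps residue pairs to
    scores and must be symmetric; when None, ``match``/``mismatch`` apply to
    any residue pair.
    """

    substitution: dict[tuple[str, str], float] | None = None
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")
        if self.substitution is not None:
            for (a, b), v in self.substitution.items():
                if self.substitution.get((b, a), v) != v:
                    raise ValueError(f"substitution map asymmetric at ({a}, {b})")

    @classmethod
    def blosum62(cls, gap_open: float = 10.0, gap_extend: float = 1.0) -> "SwParams":
        """Default protein scoring: BLOSUM62 with affine gaps (open 10, extend 1)."""
        table = substitution_matrices.load("BLOSUM62")
        sub = {
            (a, b): float(table[a, b])
            for a in table.alphabet
            for b in table.alphabet
        }
        return cls(substitution=sub, gap_open=gap_open, gap_extend=gap_extend)


@dataclass
class ScoreSet:
    """The masked score matrices entering the loss.

    ``s_c`` is N_d x N_t with observed entries equal to the interaction
    score (default 0.9) and NaN elsewhere; ``s_d`` / ``s_t`` hold
    within-domain similarities in [0, 1], NaN marking masked entries.
    """

    s_c: np.ndarray
    s_d: np.ndarray
    s_t: np.ndarray

    def __post_init__(self):
        self.s_c = np.asarray(self.s_c, dtype=float)
        self.s_d = np.asarray(self.s_d, dtype=float)
        self.s_t = np.asarray(self.s_t, dtype=float)
        for name, mat in (("s_d", self.s_d), ("s_t", self.s_t)):
            obs = ~np.isnan(mat)
            vals = mat[obs]
            if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
                raise ValueError(f"{name} has observed values outside [0, 1]")
            both = obs & obs.T
            if not np.allclose(mat[both], mat.T[both], atol=1e-8):
                raise ValueError(f"{name} not symmetric on observed entries")
        c_vals = self.s_c[~np.isnan(self.s_c)]
        if c_vals.size and (c_vals.min() < -1e-12 or c_vals.max() > 1 + 1e-12):
            raise ValueError("s_c has observed values outside [0, 1]")

    @property
    def mask_c(self) -> np.ndarray:
        return ~np.isnan(self.s_c)

    @property
    def mask_d(self) -> np.ndarray:
        return ~np.isnan(self.s_d)

    @property
    def mask_t(self) -> np.ndarray:
        return ~np.isnan(self.s_t)

    @property
    def n_observed_interactions(self) -> int:
        return int(self.mask_c.sum())


def build_interaction_scores(
    adjacency: np.ndarray, interaction_score: float = DEFAULT_INTERACTION_SCORE
) -> np.ndarray:
    """Map a binary adjacency matrix to interaction scores.

    Ones become ``interaction_score`` (observed), zeros become NaN
    (unobserved); the observed count equals the adjacency sum.
    """
    adj = np.asarray(adjacency, dtype=float)
    if not np.all(np.isin(adj, (0.0, 1.0))):
        bad = np.argwhere(~np.isin(adj, (0.0, 1.0)))[0]
        raise ValueError(
            f"adjacency must be binary; offending entry at {tuple(bad)}"
        )
    return np.where(adj == 1.0, interaction_score, np.nan)


def jaccard_similarity(a: SubstructureSet, b: SubstructureSet) -> float:
    """Jaccard coefficient |a n b| / |a u b| over substructure sets."""
    sa, sb = a.substructures, b.substructures
    union = sa | sb
    if not union:
        raise ValueError(
            f"similarity undefined: both {a.drug_id} and {b.drug_id} "
            "have empty substructure sets"
        )
    return len(sa & sb) / len(union)


def _aligner(p: SwParams, alphabet: str | None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if p.substitution is not None:
        letters = sorted({c for pair in p.substitution for c in pair})
        table = substitution_matrices.Array(alphabet="".join(letters), dims=2)
        for (x, y), v in p.substitution.items():
            table[x, y] = v
            table[y, x] = v
        aligner.substitution_matrix = table
    else:
        aligner.match_score = p.match
        aligner.mismatch_score = p.mismatch
        if alphabet:
            aligner.alphabet = alphabet
    aligner.open_gap_score = -p.gap_open
    aligner.extend_gap_score = -p.gap_extend
    return aligner


def smith_waterman(seq_a: str, seq_b: str, p: SwParams | None = None) -> float:
    """Optimal local-alignment score between two residue strings.

    Affine gaps per ``p`` (linear when gap_extend == gap_open); always >= 0
    and symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    p = p or SwParams.blosum62()
    aligner = _aligner(p, alphabet=None)
    try:
        return float(aligner.score(seq_a, seq_b))
    except ValueError as exc:
        raise ValueError(f"unknown residue token: {exc}") from exc


def normalized_sw(seq_a: str, seq_b: str, p: SwParams | None = None) -> float:
    """Smith-Waterman score normalized by the geometric mean of self-scores.

    SW(a, b) / sqrt(SW(a, a) * SW(b, b)); equals 1 for identical sequences
    and lies in [0, 1] under standard scoring.
    """
    p = p or SwParams.blosum62()
    self_a = smith_waterman(seq_a, seq_a, p)
    self_b = smith_waterman(seq_b, seq_b, p)
    if self_a <= 0 or self_b <= 0:
        raise ValueError("zero self-alignment score; normalization undefined")
    return smith_waterman(seq_a, seq_b, p) / np.sqrt(self_a * self_b)


def dataset_sparsity(n_drugs: int, n_targets: int, n_interactions: int) -> float:
    """Percentage of drug-target pairs with no known interaction, to 2 decimals."""
    if n_drugs <= 0 or n_targets <= 0:
        raise ValueError("drug and target counts must be positive")
    total = n_drugs * n_targets
    if n_interactions > total:
        raise ValueError("more interactions than pairs")
    return round(100.0 * (1.0 - n_interactions / total), 2)


def validate_similarity_matrix(
    mat: np.ndarray, name: str = "similarity", diag_tol: float = 1e-6
) -> np.ndarray:
    """Check a supplied similarity matrix and force an exact unit diagonal.

    Diagonal entries within ``diag_tol`` of 1 are snapped to 1; anything
    further off is rejected as un-normalized input.  NaN entries are allowed
    (masked), observed entries must lie in [0, 1] and be symmetric.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} matrix must be square")
    diag = np.diag(mat)
    observed_diag = ~np.isnan(diag)
    if np.any(np.abs(diag[observed_diag] - 1.0) > diag_tol):
        bad = int(np.argmax(np.abs(np.nan_to_num(diag, nan=1.0) - 1.0)))
        raise ValueError(
            f"{name} diagonal entry {bad} is {diag[bad]!r}, not 1 within {diag_tol}"
        )
    out = mat.copy()
    np.fill_diagonal(out, np.where(observed_diag, 1.0, np.diag(out)))
    obs = ~np.isnan(out)
    vals = out[obs]
    if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
        raise ValueError(f"{name} has values outside [0, 1]")
    both = obs & obs.T
    if not np.allclose(out[both], out.T[both], atol=1e-6):
        raise ValueError(f"{name} asymmetric beyond 1e-6")
    sym = out.copy()
    sym[both] = (out[both] + out.T[both]) / 2.0  # NaN-safe symmetrization
    return sym
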