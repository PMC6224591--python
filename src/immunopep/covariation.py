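"""Inter-position statistical coupling of fixed-length peptide sets.

Coupling between two sites measures how much the residue frequencies at one
site shift when the peptide set is conditioned (perturbed) on a residue at a
second site.  For sites i and j the perturbation of fixing residue x at i
contributes a log-ratio RMS divergence

    D(i->j | x) = sqrt( sum_a [ ln( f~_j|x(a) / f~_j(a) ) ]^2 )

over the 20 residues; the coupling value is the count-weighted sum over all
perturbations x whose subset holds at least ``n_min`` peptides.  Frequencies
are regularised as a mixture with the uniform distribution,

    f~(a) = (1 - w) f(a) + w / 20,

which keeps every log-ratio finite while depending only on frequencies, not
raw counts: a site with a constant residue couples exactly 0 to every other
site, and duplicating the dataset leaves the matrix unchanged.  The diagonal
carries per-position conservation, the same RMS divergence of the position's
frequencies from a background (the repertoire's own pooled composition by
default).  The matrix is not forced symmetric; ``symmetrised`` averages the
two directions for display and ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import AA_INDEX
from .io import Repertoire
from .motif import ReferenceFrequencies

#: Default weight of the uniform component in the frequency regularisation.
DEFAULT_PSEUDO_WEIGHT = 0.05


@dataclass
class CouplingMatrix:
    length: int
    values: pd.DataFrame  # L x L, rows/cols = positions 1..L
    n: int
    pseudo_weight: float
    n_min: int

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("coupling values must be finite and non-negative")

    def symmetrised(self) -> pd.DataFrame:
        """Mean of the matrix and its transpose (diagonal unchanged)."""
        v = self.values.to_numpy()
        sym = (v + v.T) / 2.0
        return pd.DataFrame(sym, index=self.values.index, columns=self.values.columns)


def _seq_matrix(seqs: list[str], length: int) -> np.ndarray:
    mat = np.empty((len(seqs), length), dtype=np.int8)
    for r, s in enumerate(seqs):
        for c, aa in enumerate(s):
            mat[r, c] = AA_INDEX[aa]
    return mat


def default_n_min(n: int) -> int:
    """Minimum perturbation-subset size: 10 or 5% of n, whichever is larger."""
    return max(10, int(np.ceil(0.05 * n)))


def _regularise(freqs: np.ndarray, w: float) -> np.ndarray:
    return (1.0 - w) * freqs + w / 20.0


def coupling_matrix(
    rep: Repertoire | list[str],
    length: int,
    n_min: int | None = None,
    pseudo_weight: float = DEFAULT_PSEUDO_WEIGHT,
    background: ReferenceFrequencies | None = None,
) -> CouplingMatrix:
    """Compute the L x L coupling/conservation matrix for one peptide length.

    ``background`` sets the reference for the diagonal conservation terms;
    by default the repertoire's own all-position pooled frequencies are used.
    """
    if not 0.0 < pseudo_weight < 1.0:
        raise ValueError("pseudo_weight must be in (0, 1)")
    seqs = rep.sequences(length) if isinstance(rep, Repertoire) else [s for s in rep if len(s) == length]
    n = len(seqs)
    if n_min is None:
        n_min = default_n_min(n)
    if n < n_min:
        raise ValueError(f"only {n} peptides of length {length}; need >= {n_min}")
    mat = _seq_matrix(seqs, length)

    counts = np.zeros((length, 20), dtype=float)
    for j in range(length):
        counts[j] = np.bincount(mat[:, j], minlength=20)
    f_marg = _regularise(counts / n, pseudo_weight)

    if background is None:
        pooled = counts.sum(axis=0)
        q = _regularise(pooled / pooled.sum(), pseudo_weight)
    else:
        q = _regularise(background.freqs.to_numpy(), pseudo_weight)

    values = np.zeros((length, length), dtype=float)
    for i in range(length):
        for x in range(20):
            sel = mat[:, i] == x
            n_x = int(sel.sum())
            if n_x < n_min:
                continue
            sub = mat[sel]
            w = n_x / n
            for j in range(length):
                if j == i:
                    continue
                c_sub = np.bincount(sub[:, j], minlength=20)
                f_cond = _regularise(c_sub / n_x, pseudo_weight)
                d = np.sqrt(np.sum(np.log(f_cond / f_marg[j]) ** 2))
                values[i, j] += w * d
    for j in range(length):
        values[j, j] = np.sqrt(np.sum(np.log(f_marg[j] / q) ** 2))

    df = pd.DataFrame(values, index=range(1, length + 1), columns=range(1, length + 1))
    return CouplingMatrix(length, df, n, pseudo_weight, n_min)


def top_coupled_pairs(m: CouplingMatrix, k: int) -> list[tuple[int, int, float]]:
    """Top-k off-diagonal position pairs (i < j) of the symmetrised matrix,
    descending by value with deterministic (i, j) tie-break.  A ``k`` beyond
    the number of pairs returns all pairs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sym = m.symmetrised().to_numpy()
    pairs = [
        (i + 1, j + 1, float(sym[i, j]))
        for i in range(m.length)
        for j in range(i + 1, m.length)
    ]
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return pairs[:k]


def permutation_null(
    rep: Repertoire | list[str],
    length: int,
    n_permutations: int = 50,
    rng: np.random.Generator | None = None,
    per_pair: bool = False,
    **kwargs,
) -> np.ndarray:
    """Coupling values under independent positions.

    Each permutation shuffles every column of the sequence matrix
    independently, destroying inter-position structure while preserving
    marginals, and recomputes the coupling matrix.  Returns the pooled
    off-diagonal values across permutations, or with ``per_pair=True`` the
    full stack of null matrices (n_permutations x L x L) so each pair can be
    compared against its own null distribution.
    """
    rng = rng or np.random.default_rng(0)
    seqs = rep.sequences(length) if isinstance(rep, Repertoire) else [s for s in rep if len(s) == length]
    arr = np.array([list(s) for s in seqs])
    out = []
    mask = ~np.eye(length, dtype=bool)
    for _ in range(n_permutations):
        perm = arr.copy()
        for j in range(length):
            rng.shuffle(perm[:, j])
        shuffled = ["".join(row) for row in perm]
        cm = coupling_matrix(shuffled, length, **kwargs)
        v = cm.values.to_numpy()
        out.append(v if per_pair else v[mask])
    return np.stack(out) if per_pair else np.concatenate(out)
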