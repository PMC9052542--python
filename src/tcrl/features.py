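"""Amino-acid composition features, biochemical property weights, and diversity.

Each subject's repertoire is summarised as the proportion of each of the
20 standard amino acids among all residues, weighted by clone abundance:
a sequence counted with abundance w contributes w copies of each of its
residues. Stacking these per-subject proportion vectors gives a
structured n x 20 feature matrix regardless of how many (or which)
sequences each subject carries. A p x r weight matrix of known
biochemical properties (hydrophobicity by default) maps the composition
onto r interpretable scores per subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .repertoire_io import AMINO_ACIDS, Repertoire, RepertoireSet

#: Kyte-Doolittle hydropathy index, keyed by one-letter amino-acid code.
#: Positive values are hydrophobic, negative hydrophilic.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

_AA_INDEX = {aa: j for j, aa in enumerate(AMINO_ACIDS)}


def amino_acid_counts(rep: Repertoire, alphabet: str = AMINO_ACIDS) -> np.ndarray:
    """Abundance-weighted residue counts g_j for one repertoire.

    ``g_j = sum_k w_k * (# occurrences of amino acid j in sequence k)``,
    so a sequence observed w times contributes w copies of each residue.
    """
    idx = {aa: j for j, aa in enumerate(alphabet)}
    counts = np.zeros(len(alphabet), dtype=float)
    for seq, w in zip(rep.sequences, rep.abundances):
        for ch in seq:
            counts[idx[ch]] += w
    return counts


def feature_vector(counts: np.ndarray) -> np.ndarray:
    """Normalize residue counts to proportions summing to one."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero count vector (empty repertoire)")
    return counts / total


def feature_matrix(rs: RepertoireSet, alphabet: str = AMINO_ACIDS) -> np.ndarray:
    """n x p matrix of per-subject amino-acid proportions (rows sum to 1)."""
    return np.vstack([feature_vector(amino_acid_counts(r, alphabet)) for r in rs])


def default_weight_matrix(alphabet: str = AMINO_ACIDS) -> np.ndarray:
    """The default p x 1 property-weight matrix: Kyte-Doolittle hydropathy."""
    return np.array([[KYTE_DOOLITTLE[aa]] for aa in alphabet], dtype=float)


def read_weight_matrix(path, *, sep: str = "\t", col_aa: str = "amino_acid"):
    """Read a custom weight matrix: amino-acid column + one column per property.

    Rows are reindexed to the canonical alphabetical amino-acid order;
    all 20 standard residues must be present.

    Returns
    -------
    (numpy.ndarray, list of str)
        The p x r weight matrix and the r property names.
    """
    df = pd.read_csv(path, sep=sep)
    if col_aa not in df.columns:
        raise ValueError(f"weight-matrix file missing column {col_aa!r}")
    df = df.set_index(col_aa)
    missing = [aa for aa in AMINO_ACIDS if aa not in df.index]
    if missing:
        raise ValueError(f"weight-matrix file missing amino acids {missing}")
    df = df.loc[list(AMINO_ACIDS)]
    W = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError("weight matrix contains non-finite entries")
    return W, list(df.columns)


def weighted_features(F: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Property-weighted features: row i of the result is W' f(R_i).

    With the hydropathy weight column this is each subject's
    composition-weighted mean hydrophobicity.
    """
    F = np.asarray(F, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    if F.shape[1] != W.shape[0]:
        raise ValueError(
            f"feature matrix has {F.shape[1]} columns but weight matrix has "
            f"{W.shape[0]} rows"
        )
    return F @ W


def shannon_entropy(rep: Repertoire) -> float:
    """Shannon entropy (natural log) of a repertoire's clone-abundance distribution.

    Zero for a single clone; ln(m) for m equally abundant clones. Higher
    values mean a more even, more diverse repertoire.
    """
    q = rep.abundances / rep.abundances.sum()
    return float(-(q * np.log(q)).sum())
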