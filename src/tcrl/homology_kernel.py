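"""Repertoire homology kernel from pairwise global sequence alignment.

Two CDR3 amino-acid sequences a and b are aligned globally
(Needleman-Wunsch with affine gap penalties) under a substitution matrix
(BLOSUM62 or PAM250), giving a raw alignment score d(a, b). The score is
normalized by the geometric mean of the self-alignment scores,

    s(a, b) = d(a, b) / sqrt(d(a, a) d(b, b)),

so s(a, a) = 1 and s can drop below zero for highly dissimilar pairs
(negative substitution values and gap penalties dominating); negative
values are retained, not clipped.

Repertoire-level homology between subjects i and j is an
abundance-weighted best-match average: each sequence of repertoire i
finds its best match in repertoire j (and vice versa), each best-match
homology is weighted by the clone abundance of the query sequence, and
the grand total is divided by the combined clone count of the two
repertoires:

    S_ij = [ sum_k w_ik max_l s(a_ik, a_jl) + sum_l w_jl max_k s(a_ik, a_jl) ]
           / ( sum_k w_ik + sum_l w_jl ).

This normalization is the one under which the kernel is exactly
symmetric and has a unit diagonal for arbitrary abundances: within a
subject every sequence's best match is itself, so both weighted sums
collapse to the total clone count. The resulting n x n matrix is not
guaranteed positive semi-definite; negative eigenvalues are zeroed by a
low-rank eigenvalue truncation before the kernel is used as a
random-effect covariance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .repertoire_io import AMINO_ACIDS, Repertoire, RepertoireSet, validate_sequence

SUPPORTED_MATRICES = ("BLOSUM62", "PAM250")


@dataclass(frozen=True)
class SubstitutionScheme:
    """Alignment scoring scheme: substitution matrix plus affine gap penalties.

    A gap of length L is penalized ``gap_open + gap_extend * (L - 1)``.
    The defaults (10, 0.5) are the EMBOSS needle defaults for global
    protein alignment under BLOSUM62/PAM250.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        name = self.matrix_name.upper()
        object.__setattr__(self, "matrix_name", name)
        if name not in SUPPORTED_MATRICES:
            raise ValueError(
                f"unsupported substitution matrix {name!r}; "
                f"choose from {SUPPORTED_MATRICES}"
            )
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    def aligner(self) -> Align.PairwiseAligner:
        """A configured global pairwise aligner for this scheme."""
        return _make_aligner(self.matrix_name, self.gap_open, self.gap_extend)


@lru_cache(maxsize=8)
def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # Biopython charges open_gap_score for the first gap position and
    # extend_gap_score for each subsequent one: open + extend*(L-1).
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


@dataclass
class HomologyKernel:
    """n x n repertoire-homology matrix with provenance metadata."""

    S: np.ndarray
    subject_ids: list[str]
    scheme: SubstitutionScheme
    #: eigen-repair report: filled in by :func:`psd_project`
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = self.S.shape[0]
        if self.S.shape != (n, n) or n != len(self.subject_ids):
            raise ValueError("kernel must be square and match subject IDs")

    @property
    def n(self) -> int:
        return self.S.shape[0]

    def write(self, path) -> None:
        """Write the kernel as TSV (subject-ID header row/column) + JSON sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.S, index=self.subject_ids, columns=self.subject_ids)
        df.to_csv(path, sep="\t", index_label="subject_id", float_format="%.17g")
        sidecar = {
            "matrix_name": self.scheme.matrix_name,
            "gap_open": self.scheme.gap_open,
            "gap_extend": self.scheme.gap_extend,
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )

    @classmethod
    def read(cls, path) -> "HomologyKernel":
        """Read a kernel written by :meth:`write`."""
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="subject_id")
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        scheme = SubstitutionScheme(
            matrix_name=sidecar["matrix_name"],
            gap_open=sidecar["gap_open"],
            gap_extend=sidecar["gap_extend"],
        )
        return cls(
            S=df.to_numpy(dtype=float),
            subject_ids=[str(s) for s in df.index],
            scheme=scheme,
            meta=sidecar.get("meta", {}),
        )


def align_score(a: str, b: str, scheme: SubstitutionScheme) -> float:
    """Optimal global (Needleman-Wunsch) alignment score d(a, b)."""
    validate_sequence(a)
    validate_sequence(b)
    return float(scheme.aligner().score(a, b))


def sequence_homology(a: str, b: str, scheme: SubstitutionScheme) -> float:
    """Self-score-normalized homology s(a, b); 1 iff a == b, may be negative."""
    if a == b:
        return 1.0
    daa = align_score(a, a, scheme)
    dbb = align_score(b, b, scheme)
    for seq, d in ((a, daa), (b, dbb)):
        if d <= 0:
            raise ValueError(
                f"non-positive self-alignment score {d} for sequence {seq!r}; "
                "cannot normalize"
            )
    return align_score(a, b, scheme) / np.sqrt(daa * dbb)


def repertoire_homology(
    ri: Repertoire, rj: Repertoire, scheme: SubstitutionScheme,
) -> float:
    """Abundance-weighted best-match homology S_ij between two repertoires."""
    aligner = scheme.aligner()
    self_i = np.array([aligner.score(s, s) for s in ri.sequences])
    self_j = np.array([aligner.score(s, s) for s in rj.sequences])
    for seqs, selfs in ((ri.sequences, self_i), (rj.sequences, self_j)):
        bad = np.flatnonzero(selfs <= 0)
        if bad.size:
            raise ValueError(
                f"non-positive self-alignment score for sequence {seqs[bad[0]]!r}"
            )
    # s matrix for all cross pairs; each alignment computed once
    smat = np.empty((ri.m, rj.m))
    for k, a in enumerate(ri.sequences):
        for l, b in enumerate(rj.sequences):
            if a == b:
                smat[k, l] = 1.0
            else:
                smat[k, l] = aligner.score(a, b) / np.sqrt(self_i[k] * self_j[l])
    wi = ri.abundances.astype(float)
    wj = rj.abundances.astype(float)
    num = wi @ smat.max(axis=1) + wj @ smat.max(axis=0)
    return float(num / (wi.sum() + wj.sum()))


def build_kernel(rs: RepertoireSet, scheme: SubstitutionScheme) -> HomologyKernel:
    """Compute the raw repertoire-homology kernel for a cohort.

    The diagonal is set to 1 analytically (every within-subject best
    match is the sequence itself). Alignments are shared across subject
    pairs by computing the normalized homology once for every pair of
    distinct sequences in the cohort.
    """
    if rs.n < 2:
        raise ValueError("kernel requires at least 2 subjects")
    aligner = scheme.aligner()

    # index all distinct sequences in the cohort
    seq_index: dict[str, int] = {}
    for rep in rs:
        for s in rep.sequences:
            seq_index.setdefault(s, len(seq_index))
    seqs = list(seq_index)
    u = len(seqs)

    self_scores = np.array([aligner.score(s, s) for s in seqs])
    bad = np.flatnonzero(self_scores <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive self-alignment score for sequence {seqs[bad[0]]!r}"
        )
    inv_sqrt_self = 1.0 / np.sqrt(self_scores)

    smat = np.empty((u, u))
    np.fill_diagonal(smat, 1.0)
    score = aligner.score
    for p in range(u):
        sp = seqs[p]
        row = smat[p]
        for q in range(p + 1, u):
            row[q] = score(sp, seqs[q])
        smat[p + 1:, p] = row[p + 1:]
    norm = np.outer(inv_sqrt_self, inv_sqrt_self)
    off = ~np.eye(u, dtype=bool)
    smat[off] *= norm[off]

    idx = [np.array([seq_index[s] for s in rep.sequences]) for rep in rs]
    w = [rep.abundances.astype(float) for rep in rs]
    wtot = np.array([wi.sum() for wi in w])

    S = np.eye(rs.n)
    for i in range(rs.n):
        sub_i = smat[idx[i]]
        for j in range(i + 1, rs.n):
            block = sub_i[:, idx[j]]
            num = w[i] @ block.max(axis=1) + w[j] @ block.max(axis=0)
            S[i, j] = S[j, i] = num / (wtot[i] + wtot[j])
    return HomologyKernel(S=S, subject_ids=rs.subject_ids, scheme=scheme)


def psd_project(kernel: HomologyKernel, tol: float = 1e-10) -> HomologyKernel:
    """Project the kernel onto the positive semi-definite cone.

    Eigendecomposes S, zeroes negative eigenvalues, and reconstructs from
    the non-negative part of the spectrum. If the minimum eigenvalue is
    already >= -tol the kernel is returned unchanged (making the
    operation idempotent). The repair report (number of clipped
    eigenvalues, most negative eigenvalue) is stored in ``meta``.
    """
    S = kernel.S
    if not np.allclose(S, S.T, atol=1e-12):
        raise ValueError("kernel must be symmetric before PSD projection")
    eigval, eigvec = np.linalg.eigh(S)
    min_eig = float(eigval[0])
    if min_eig >= -tol:
        kernel.meta.setdefault("eigen_repair", {
            "n_clipped": 0, "min_eigenvalue": min_eig,
        })
        return kernel
    clipped = eigval < 0
    eigval_pos = np.where(clipped, 0.0, eigval)
    S_psd = (eigvec * eigval_pos) @ eigvec.T
    S_psd = (S_psd + S_psd.T) / 2.0
    meta = dict(kernel.meta)
    meta["eigen_repair"] = {
        "n_clipped": int(clipped.sum()),
        "min_eigenvalue": min_eig,
    }
    return HomologyKernel(
        S=S_psd, subject_ids=list(kernel.subject_ids),
        scheme=kernel.scheme, meta=meta,
    )
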