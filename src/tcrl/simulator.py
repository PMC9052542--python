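"""Synthetic TCR repertoire cohorts and Monte-Carlo operating characteristics.

CDR3 sequences are generated as head + middle + tail: a four-residue
head drawn from {CASS, CASR, CSAR, CAST} with probabilities
(0.7, 0.1, 0.1, 0.1), a middle of 4-10 residues sampled uniformly with
replacement from the 20 amino acids, into which 0-2 additional residues
are inserted (emulating P/N nucleotide addition), and a two-residue tail
from {YF, FF, HF, TF} with probabilities (0.4, 0.4, 0.1, 0.1). Total
lengths therefore range from 10 to 18. A subject's repertoire holds
2-25 unique sequences with clone abundances 1-5.

Traits are generated from the mixed model with confounders
X1 ~ Bernoulli(0.5), X2 ~ N(0, 1) and coefficients
beta = (0.1, 0.5, -0.4); the fixed repertoire effect acts through the
hydropathy-weighted composition and the random effect h ~ N(0, tau^2 S)
through the homology kernel of the generated cohort. Continuous traits
add N(0, 1) noise; binary traits are Bernoulli draws on the logit scale,
redrawn (outcome only) until each class holds at least 10% of subjects.

``run_study`` drives replicated type-I-error and power studies over the
five analysis strategies: the fixed-effect-only test of the extracted
features ("ext_features"), the random-effect-only tests under each
substitution matrix ("seq_b62", "seq_p250"), and the combined
mixed-effects tests ("tcrl_b62", "tcrl_p250").
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .association_test import (
    fisher_combine,
    fit_null_h0,
    fit_null_h0prime,
    score_fixed,
    score_random,
)
from .features import default_weight_matrix, feature_matrix, weighted_features
from .homology_kernel import HomologyKernel, SubstitutionScheme, build_kernel, psd_project
from .repertoire_io import (
    AMINO_ACIDS,
    CovariateTable,
    PhenotypeVector,
    Repertoire,
    RepertoireSet,
)

HEAD_TABLE: dict[str, float] = {"CASS": 0.7, "CASR": 0.1, "CSAR": 0.1, "CAST": 0.1}
TAIL_TABLE: dict[str, float] = {"YF": 0.4, "FF": 0.4, "HF": 0.1, "TF": 0.1}

#: default effect sizes per (scenario, trait_type)
DEFAULT_EFFECTS: dict[tuple[str, str], dict[str, float]] = {
    ("fixed_only", "binary"): {"eta": 1.6, "tau2": 0.0},
    ("fixed_only", "continuous"): {"eta": 0.8, "tau2": 0.0},
    ("random_only", "binary"): {"eta": 0.0, "tau2": 8.0},
    ("random_only", "continuous"): {"eta": 0.0, "tau2": 0.8},
    ("both", "binary"): {"eta": 1.0, "tau2": 6.0},
    ("both", "continuous"): {"eta": 0.5, "tau2": 0.6},
    ("null", "binary"): {"eta": 0.0, "tau2": 0.0},
    ("null", "continuous"): {"eta": 0.0, "tau2": 0.0},
}

METHODS = ("ext_features", "seq_b62", "seq_p250", "tcrl_b62", "tcrl_p250")


@dataclass
class SimulationConfig:
    """Study conditions for a replicated simulation.

    ``eta``/``tau2`` default to the scenario- and trait-specific effect
    sizes in :data:`DEFAULT_EFFECTS` when left as None.
    """

    n: int = 200
    trait_type: str = "binary"
    scenario: str = "null"
    replicates: int = 100
    seed: int = 0
    eta: float | None = None
    tau2: float | None = None
    beta: tuple[float, float, float] = (0.1, 0.5, -0.4)
    gen_matrix: str = "BLOSUM62"       # substitution matrix generating h
    alpha: float = 0.05
    imbalance_floor: float = 0.10
    fixed_cohort: bool = False
    # repertoire-generation parameters
    unique_range: tuple[int, int] = (2, 25)
    abundance_range: tuple[int, int] = (1, 5)
    middle_range: tuple[int, int] = (4, 10)
    insertion_counts: tuple[int, ...] = (0, 1, 2)
    head_table: dict[str, float] = field(default_factory=lambda: dict(HEAD_TABLE))
    tail_table: dict[str, float] = field(default_factory=lambda: dict(TAIL_TABLE))

    def __post_init__(self) -> None:
        if self.scenario not in ("null", "fixed_only", "random_only", "both"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        for table, label in ((self.head_table, "head"), (self.tail_table, "tail")):
            if abs(sum(table.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} probabilities must sum to 1")
        if self.tau2 is not None and self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        defaults = DEFAULT_EFFECTS[(self.scenario, self.trait_type)]
        if self.eta is None:
            self.eta = defaults["eta"]
        if self.tau2 is None:
            self.tau2 = defaults["tau2"]


def simulate_cdr3(rng: np.random.Generator, config: SimulationConfig | None = None) -> str:
    """Draw one CDR3 amino-acid sequence (length 10-18, C...F)."""
    cfg = config or _DEFAULT_CFG
    heads = list(cfg.head_table)
    head = heads[rng.choice(len(heads), p=[cfg.head_table[h] for h in heads])]
    tails = list(cfg.tail_table)
    tail = tails[rng.choice(len(tails), p=[cfg.tail_table[t] for t in tails])]
    mid_len = int(rng.integers(cfg.middle_range[0], cfg.middle_range[1] + 1))
    middle = list(rng.choice(list(AMINO_ACIDS), size=mid_len))
    n_ins = int(cfg.insertion_counts[rng.integers(len(cfg.insertion_counts))])
    for _ in range(n_ins):
        pos = int(rng.integers(len(middle) + 1))
        middle.insert(pos, str(rng.choice(list(AMINO_ACIDS))))
    return head + "".join(middle) + tail


def simulate_repertoire_set(
    n: int, rng: np.random.Generator, config: SimulationConfig | None = None,
) -> RepertoireSet:
    """Generate a cohort of n repertoires (2-25 unique sequences, abundances 1-5)."""
    if n < 2:
        raise ValueError("need at least 2 subjects")
    cfg = config or _DEFAULT_CFG
    lo, hi = cfg.unique_range
    alo, ahi = cfg.abundance_range
    reps = []
    for i in range(n):
        m = int(rng.integers(lo, hi + 1))
        seqs: list[str] = []
        seen: set[str] = set()
        while len(seqs) < m:
            s = simulate_cdr3(rng, cfg)
            if s not in seen:      # redraw on collision to keep sequences unique
                seen.add(s)
                seqs.append(s)
        w = rng.integers(alo, ahi + 1, size=m)
        reps.append(Repertoire(subject_id=f"S{i + 1}", sequences=seqs, abundances=w))
    return RepertoireSet(reps)


def simulate_covariates(n: int, rng: np.random.Generator) -> CovariateTable:
    """Two confounders: X1 ~ Bernoulli(0.5), X2 ~ N(0, 1), plus intercept."""
    X1 = rng.binomial(1, 0.5, size=n).astype(float)
    X2 = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), X1, X2])
    ids = [f"S{i + 1}" for i in range(n)]
    return CovariateTable(X=X, subject_ids=ids, names=["intercept", "x1", "x2"])


def _random_effect(tau2: float, S_gen: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw h ~ N(0, tau2 * S) via the eigen factor of the PSD kernel."""
    eigval, eigvec = np.linalg.eigh(S_gen)
    if eigval[0] < -1e-8:
        raise ValueError("generating kernel is not positive semi-definite")
    eigval = np.clip(eigval, 0.0, None)
    factor = eigvec * np.sqrt(tau2 * eigval)
    return factor @ rng.standard_normal(S_gen.shape[0])


def simulate_trait(
    rs: RepertoireSet,
    cov: CovariateTable,
    scenario: str,
    config: SimulationConfig,
    S_gen: np.ndarray | HomologyKernel | None,
    rng: np.random.Generator,
    *,
    G: np.ndarray | None = None,
    h: np.ndarray | None = None,
) -> PhenotypeVector:
    """Generate a trait from the mixed model under the given scenario.

    The linear predictor is beta'X plus, per scenario, the fixed
    composition effect eta * (hydropathy score) and/or the random effect
    h ~ N(0, tau2 * S_gen). For binary traits the outcome vector is
    redrawn (covariates, repertoires, and h held fixed) until both
    classes contain at least ``ceil(imbalance_floor * n)`` subjects.

    ``G`` (precomputed weighted features) and ``h`` (a pre-drawn random
    effect) may be supplied to keep replicate loops cheap.
    """
    n = rs.n
    lp = cov.X @ np.asarray(config.beta, dtype=float)
    if scenario in ("fixed_only", "both"):
        if G is None:
            G = weighted_features(feature_matrix(rs), default_weight_matrix())
        lp = lp + config.eta * G[:, 0]
    if scenario in ("random_only", "both"):
        if h is None:
            if S_gen is None:
                raise ValueError("scenario with a random effect requires S_gen")
            S = S_gen.S if isinstance(S_gen, HomologyKernel) else np.asarray(S_gen)
            h = _random_effect(config.tau2, S, rng)
        lp = lp + h

    if config.trait_type == "continuous":
        y = lp + rng.standard_normal(n)
    else:
        prob = 1.0 / (1.0 + np.exp(-lp))
        floor = int(np.ceil(config.imbalance_floor * n))
        for _ in range(1000):
            y = rng.binomial(1, prob).astype(float)
            k = int(y.sum())
            if min(k, n - k) >= floor:
                break
        else:
            raise RuntimeError(
                "could not satisfy the class-balance floor in 1000 outcome redraws"
            )
    return PhenotypeVector(y=y, trait_type=config.trait_type, subject_ids=rs.subject_ids)


_DEFAULT_CFG = SimulationConfig()


@dataclass
class StudyResult:
    """Rejection rates, per-replicate p-values, and run metadata."""

    rates: pd.DataFrame
    pvalues: dict[str, np.ndarray]
    meta: dict

    def write(self, rates_path, meta_path=None) -> None:
        self.rates.to_csv(rates_path, sep="\t", index=False)
        if meta_path is not None:
            import json
            from pathlib import Path
            Path(meta_path).write_text(json.dumps(self.meta, indent=2) + "\n")


def _analyze_replicate(X, G, y, trait, kernels) -> dict[str, float]:
    """Run the five analysis strategies on one replicate; returns p-values."""
    fit0 = fit_null_h0(X, y, trait)
    _, p_ext = score_fixed(fit0, G, y)
    fitX = fit_null_h0prime(X, None, y, trait)
    fitG = fit_null_h0prime(X, G, y, trait)
    out = {"ext_features": p_ext}
    for tag, S in kernels.items():
        _, p_seq = score_random(fitX, S)
        out[f"seq_{tag}"] = p_seq
        _, p_rand = score_random(fitG, S)
        # component p-value entering the Fisher combination; kept so the
        # independence of the two scores can be checked empirically
        out[f"rand_{tag}"] = p_rand
        _, p_comb = fisher_combine(p_ext, p_rand)
        out[f"tcrl_{tag}"] = p_comb
    return out


def _cohort_kernels(rs: RepertoireSet, config: SimulationConfig):
    """Analysis kernels (both matrices, PSD) and the generating kernel."""
    kernels = {}
    for tag, name in (("b62", "BLOSUM62"), ("p250", "PAM250")):
        kernels[tag] = psd_project(
            build_kernel(rs, SubstitutionScheme(matrix_name=name))
        ).S
    gen_tag = "b62" if config.gen_matrix.upper() == "BLOSUM62" else "p250"
    return kernels, kernels[gen_tag]


def run_study(config: SimulationConfig) -> StudyResult:
    """Monte-Carlo rejection-rate study under one scenario.

    Each replicate generates repertoires, covariates, and a trait, builds
    both analysis kernels, and runs the five strategies; empirical
    rejection rates at ``config.alpha`` are reported with binomial
    Monte-Carlo standard errors. With ``fixed_cohort=True`` the
    repertoires, covariates, and kernels are drawn once and only the
    trait (and random effect) is redrawn per replicate — an approximation
    that trades cohort-level variability for a large speedup.
    """
    rng = np.random.default_rng(config.seed)
    tracked = list(METHODS) + ["rand_b62", "rand_p250"]
    pvals: dict[str, list[float]] = {m: [] for m in tracked}

    if config.fixed_cohort:
        rs = simulate_repertoire_set(config.n, rng, config)
        cov = simulate_covariates(config.n, rng)
        G = weighted_features(feature_matrix(rs), default_weight_matrix())
        kernels, S_gen = _cohort_kernels(rs, config)
        for _ in range(config.replicates):
            phe = simulate_trait(rs, cov, config.scenario, config, S_gen, rng, G=G)
            res = _analyze_replicate(cov.X, G, phe.y, config.trait_type, kernels)
            for m in tracked:
                pvals[m].append(res[m])
    else:
        for rep_idx in range(config.replicates):
            try:
                rs = simulate_repertoire_set(config.n, rng, config)
                cov = simulate_covariates(config.n, rng)
                G = weighted_features(feature_matrix(rs), default_weight_matrix())
                kernels, S_gen = _cohort_kernels(rs, config)
                phe = simulate_trait(rs, cov, config.scenario, config, S_gen, rng, G=G)
                res = _analyze_replicate(cov.X, G, phe.y, config.trait_type, kernels)
            except Exception as exc:
                raise RuntimeError(f"replicate {rep_idx} failed: {exc}") from exc
            for m in tracked:
                pvals[m].append(res[m])

    rows = []
    R = config.replicates
    for m in METHODS:
        p = np.asarray(pvals[m])
        rate = float(np.mean(p < config.alpha))
        se = float(np.sqrt(rate * (1.0 - rate) / R))
        rows.append({
            "method": m, "n": config.n, "trait_type": config.trait_type,
            "scenario": config.scenario, "alpha": config.alpha,
            "rejection_rate": rate, "mc_se": se, "replicates": R,
        })
    meta = asdict(config)
    meta["methods"] = list(METHODS)
    return StudyResult(
        rates=pd.DataFrame(rows),
        pvalues={m: np.asarray(v) for m, v in pvals.items()},
        meta=meta,
    )
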