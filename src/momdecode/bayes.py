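"""Bayes-factor statistics with Jeffreys-Zellner-Siow (JZS) priors.

The decoding and behaviour analyses report evidence as Bayes factors
(BF10): the marginal likelihood of the data under the alternative relative
to the null.  Three tools are provided:

* :func:`jzs_bf_ttest` — the default JZS t-test (Cauchy prior with scale
  ``r`` on the standardized effect size; Rouder et al.'s one-dimensional
  integral over the variance-mixing parameter ``g``), for one-sample,
  paired, and two-sample designs;
* :func:`bf_vs_shuffled_null` — decoding accuracy against an empirical
  label-shuffled null distribution via the two-sample JZS machinery;
* :func:`bf_anova_effect` — full-vs-restricted Bayes-factor ANOVA for a
  within-subject 2x2x2 design (attention x target frequency x time on
  task), with g-priors on standardized effect blocks, subject as an
  additive random factor, and seeded Monte-Carlo integration over the g
  parameters.

Evidence categories follow the conventional thresholds: BF10 > 10 / > 3
strong / moderate evidence for the alternative, < 1/10 and < 1/3 the
mirror-image evidence for the null, anything between 1/3 and 3
insufficient.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.special
import scipy.stats

from ._seeds import rng_for

__all__ = [
    "DEFAULT_CAUCHY_SCALE",
    "BayesFactorResult",
    "jzs_bf_ttest",
    "bf_vs_shuffled_null",
    "bf_anova_effect",
    "interpret_bf",
]

#: Default Cauchy prior scale on the standardized effect size.
DEFAULT_CAUCHY_SCALE = float(np.sqrt(2.0) / 2.0)


@dataclass
class BayesFactorResult:
    """A named Bayes factor with its evidence category."""

    bf10: float
    effect: str
    category: str
    model_full: tuple[str, ...] = ()
    model_restricted: tuple[str, ...] = ()


def interpret_bf(bf10: float) -> str:
    """Evidence category at the conventional 10 / 3 / 1/3 / 1/10 boundaries."""
    if not bf10 > 0:
        raise ValueError("bf10 must be positive")
    if bf10 > 10:
        return "strong_alt"
    if bf10 > 3:
        return "moderate_alt"
    if bf10 >= 1.0 / 3.0:
        return "insufficient"
    if bf10 >= 1.0 / 10.0:
        return "moderate_null"
    return "strong_null"


def _jzs_bf_from_t(t: float, n_eff: float, nu: float, r: float) -> float:
    """JZS BF10 from a t statistic.

    One-dimensional integral over ``g`` with the inverse-gamma(1/2, r^2/2)
    prior implied by the Cauchy(0, r) prior on the standardized effect.
    """
    t2 = t * t

    def integrand(g: float) -> float:
        a = 1.0 + n_eff * g
        log_h = (
            -0.5 * np.log(a)
            - 0.5 * (nu + 1.0) * np.log1p(t2 / (a * nu))
            + 0.5 * np.log(r * r / (2.0 * np.pi))
            - 1.5 * np.log(g)
            - r * r / (2.0 * g)
        )
        return float(np.exp(log_h))

    num, _ = scipy.integrate.quad(integrand, 0.0, np.inf, limit=200)
    log_m0 = -0.5 * (nu + 1.0) * np.log1p(t2 / nu)
    return float(num / np.exp(log_m0))


def jzs_bf_ttest(
    sample_a: np.ndarray,
    sample_b: np.ndarray | None = None,
    mu0: float = 0.0,
    paired: bool = False,
    r: float = DEFAULT_CAUCHY_SCALE,
) -> float:
    """JZS Bayes factor (BF10) for a t-test.

    One-sample against ``mu0`` when ``sample_b`` is None; paired when
    ``paired``; independent two-sample (pooled variance) otherwise.
    Deterministic given the data and the prior scale ``r``; invariant to
    rescaling the data by a positive constant.  Raises on zero variance.
    """
    a = np.asarray(sample_a, dtype=float)
    if sample_b is not None and paired:
        b = np.asarray(sample_b, dtype=float)
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        a, sample_b = a - b, None
    if sample_b is None:
        n = a.size
        if n < 2:
            raise ValueError("need n >= 2")
        sd = a.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance: t statistic undefined")
        t = (a.mean() - mu0) / (sd / np.sqrt(n))
        return _jzs_bf_from_t(float(t), float(n), float(n - 1), r)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = a.size, b.size
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per sample")
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero variance: t statistic undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    n_eff = n1 * n2 / (n1 + n2)
    return _jzs_bf_from_t(float(t), float(n_eff), float(n1 + n2 - 2), r)


def bf_vs_shuffled_null(
    actual_accuracies: np.ndarray,
    null_fn=None,
    null_samples: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    r: float = DEFAULT_CAUCHY_SCALE,
) -> float:
    """BF10 for decoding accuracies against an empirical shuffled null.

    The null distribution is either supplied (``null_samples``) or built by
    calling ``null_fn(perm_seed)`` for ``n_perm`` seeded label shuffles;
    the comparison uses the two-sample JZS t-test machinery.
    """
    if null_samples is None:
        if null_fn is None:
            raise ValueError("provide null_samples or a null_fn callback")
        seeds = [int(s) for s in rng_for(seed, "null-perms").integers(0, 2**31, n_perm)]
        null_samples = np.array([null_fn(s) for s in seeds], dtype=float)
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size < 2:
        raise ValueError("null distribution needs >= 2 values")
    return jzs_bf_ttest(np.asarray(actual_accuracies, float), null_samples, r=r)


# ---------------------------------------------------------------------------
# Bayes-factor ANOVA


def _block_columns(
    table: pd.DataFrame, factors: list[str], term: str
) -> np.ndarray:
    """Sum-to-zero design columns for a main effect or interaction term."""
    parts = term.split(":")
    cols = None
    for f in parts:
        if f not in factors:
            raise ValueError(f"unknown factor {f!r} in term {term!r}")
        levels = np.unique(table[f])
        if levels.size != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels")
        x = np.where(table[f].to_numpy() == levels[0], 1.0, -1.0)[:, None]
        cols = x if cols is None else cols * x
    return cols


def _subject_columns(table: pd.DataFrame) -> np.ndarray:
    subj = table["subject"].to_numpy()
    levels = np.unique(subj)
    X = (subj[:, None] == levels[None, :]).astype(float)
    X -= X.mean(axis=0, keepdims=True)  # intercept removed
    return X[:, :-1]  # drop one column to keep full rank


def _log_marginal(y: np.ndarray, blocks: list[np.ndarray], g: np.ndarray) -> float:
    """log m(y | g) for y ~ N(0, sigma^2 (I + sum g_b X_b X_b')) after centering.

    Jeffreys prior on sigma^2; the flat intercept is handled by centering y
    and all design columns.
    """
    n = y.size
    V = np.eye(n)
    for Xb, gb in zip(blocks, g):
        V += gb * (Xb @ Xb.T)
    sign, logdet = np.linalg.slogdet(V)
    q = float(y @ np.linalg.solve(V, y))
    return -0.5 * logdet - 0.5 * (n - 1) * np.log(q)


def _mc_log_evidence(
    y: np.ndarray,
    blocks: list[np.ndarray],
    scales: list[float],
    n_mc: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo average of m(y|g) over g_b ~ InvGamma(1/2, scale_b^2 / 2)."""
    if not blocks:
        return _log_marginal(y, [], np.empty(0))
    logs = np.empty(n_mc)
    draws = np.stack(
        [s * s / (2.0 * rng.gamma(0.5, 1.0, size=n_mc)) for s in scales], axis=1
    )
    for k in range(n_mc):
        logs[k] = _log_marginal(y, blocks, draws[k])
    return float(scipy.special.logsumexp(logs) - np.log(n_mc))


def bf_anova_effect(
    table: pd.DataFrame,
    effect: str,
    factors: list[str] | None = None,
    value_col: str = "value",
    r_fixed: float = 0.5,
    r_random: float = 1.0,
    n_mc: int = 2000,
    seed: int = 0,
) -> BayesFactorResult:
    """Full-vs-restricted Bayes-factor ANOVA for one effect.

    ``table`` is long format with a ``subject`` column, two-level factor
    columns, and ``value_col``; the design must be balanced (one value per
    subject per cell).  For a main effect the full model contains all main
    effects (plus subject) and the restricted model drops the tested
    factor; for an interaction (``"a:b"``) the full model adds the
    interaction to all main effects.  BF10 = evidence(full) /
    evidence(restricted), integrated by seeded Monte Carlo over the g
    parameters (g-priors with scale ``r_fixed`` on fixed-effect blocks and
    ``r_random`` on the subject block).
    """
    if factors is None:
        factors = [c for c in table.columns if c not in ("subject", value_col)]
    counts = table.groupby(["subject", *factors]).size()
    n_cells = table["subject"].nunique() * int(
        np.prod([table[f].nunique() for f in factors])
    )
    if len(counts) != n_cells or not (counts == 1).all():
        raise ValueError("design must be balanced: one value per subject per cell")
    y = table[value_col].to_numpy(dtype=float)
    y = y - y.mean()
    if ":" in effect:
        full_terms = [*factors, effect]
    else:
        if effect not in factors:
            raise ValueError(f"unknown effect {effect!r}")
        full_terms = list(factors)
    restricted_terms = [t for t in full_terms if t != effect]

    def build(terms: list[str]) -> tuple[list[np.ndarray], list[float]]:
        blocks = [_subject_columns(table)]
        scales = [r_random]
        for t in terms:
            blocks.append(_block_columns(table, factors, t))
            scales.append(r_fixed)
        return blocks, scales

    blocks_f, scales_f = build(full_terms)
    blocks_r, scales_r = build(restricted_terms)
    log_f = _mc_log_evidence(y, blocks_f, scales_f, n_mc, rng_for(seed, "full", effect))
    log_r = _mc_log_evidence(y, blocks_r, scales_r, n_mc, rng_for(seed, "restr", effect))
    bf10 = float(np.exp(log_f - log_r))
    return BayesFactorResult(
        bf10=bf10,
        effect=effect,
        category=interpret_bf(bf10),
        model_full=tuple(full_terms),
        model_restricted=tuple(restricted_terms),
    )
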