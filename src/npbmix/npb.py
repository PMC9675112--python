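"""Non-parametric Bayes shrinkage: a Gaussian linear model whose exposure
main effects and pairwise interaction effects carry zero-spiked
Dirichlet-process priors.

Model (outcome internally centered/scaled for sampling, summaries
back-transformed to native units):

    y_i | . ~ N(y0 + x_i' beta + z_i' zeta + w_i' gamma, sigma^2)

    beta_j  ~ G1,  G1 ~ DP(alpha1, G0_1),  G0_b = pi0_b d0 + (1-pi0_b) N(0, tau^2)
    zeta_j  ~ G2,  G2 ~ DP(alpha2, G0_2)
    gamma, y0 ~ N(0, c^2);  sigma^2 ~ Inv-Gamma(a_s, b_s)
    alpha_b ~ Gamma(a_b, b_b);  pi0_b ~ Beta(a_pi, b_pi)

The point mass at zero lets the model select exposures out exactly (the
posterior inclusion probability is the fraction of retained draws outside
the spike); the DP clusters similar coefficients onto a shared atom, which
stabilizes estimation under strong exposure correlation. Interactions are
selected by their own DP, with no heredity constraint tying them to main
effects.

The Gibbs sampler is fully conjugate: Polya-urn cluster assignment with the
zero-spiked base measure marginalized in closed form, Normal atom updates,
a joint Normal update for (gamma, y0), an inverse-gamma update for sigma^2,
Escobar-West auxiliary updates for alpha1/alpha2, and Beta updates for the
spike masses pi0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from ._gibbs import update_atoms, update_block_dp, update_block_independent
from .design import DesignMatrices

__all__ = [
    "NPBConfig",
    "NPBChain",
    "npb_fit",
    "exact_spike_slab_pip",
    "compute_pip",
    "summarize_posterior",
    "selected_terms",
    "sensitivity_sweep",
    "SweepResult",
    "convergence_report",
]


@dataclass(frozen=True)
class NPBConfig:
    """Sampler settings and prior hyperparameters.

    ``a1, b1`` / ``a2, b2``: Gamma shape/rate priors on the DP concentrations
    for the main-effect and interaction blocks (the sensitivity analysis
    sets a = b on a {0.5, 1, 2, 4} grid). ``slab_sd`` is the base-measure
    slab SD tau on the standardized-outcome scale. ``mode`` selects the full
    DP sampler or the cluster-free independent spike-and-slab limit.
    ``fix_sigma2`` / ``fix_pi0`` freeze those parameters (oracle checks).
    """

    n_iter: int = 25_000
    n_burn: int = 5_000
    thin: int = 4
    a1: float = 1.0
    b1: float = 1.0
    a2: float = 1.0
    b2: float = 1.0
    slab_sd: float = 1.0
    spike_weight_prior: tuple[float, float] = (1.0, 1.0)
    covariate_prior_sd: float = 10.0
    sigma2_prior: tuple[float, float] = (0.5, 0.5)
    seed: int = 0
    mode: str = "npb"  # "npb" | "independent_spike_slab"
    fix_sigma2: float | None = None
    fix_pi0: float | None = None
    standardize_outcome: bool = True

    def __post_init__(self) -> None:
        if self.n_iter <= self.n_burn:
            raise ValueError("n_iter must exceed n_burn")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        for name in ("a1", "b1", "a2", "b2", "slab_sd", "covariate_prior_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if min(self.spike_weight_prior) <= 0 or min(self.sigma2_prior) <= 0:
            raise ValueError("prior shape/rate parameters must be > 0")
        if self.mode not in ("npb", "independent_spike_slab"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin


@dataclass
class NPBChain:
    """Retained draws, back-transformed to the outcome's native units."""

    beta: np.ndarray  # (T, p) exposure main effects
    zeta: np.ndarray  # (T, q) interaction effects
    gamma: np.ndarray  # (T, r) covariate effects incl. intercept
    sigma2: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    pi0_main: np.ndarray
    pi0_inter: np.ndarray
    k_main: np.ndarray  # cluster counts per retained draw
    k_inter: np.ndarray
    beta_names: list[str]
    zeta_names: list[str]
    gamma_names: list[str]
    outcome: str
    config: NPBConfig
    y_center: float = 0.0
    y_scale: float = 1.0

    @property
    def n_retained(self) -> int:
        return len(self.sigma2)

    @property
    def selection_names(self) -> list[str]:
        return self.beta_names + self.zeta_names

    def selection_draws(self, term: str) -> np.ndarray:
        if term in self.beta_names:
            return self.beta[:, self.beta_names.index(term)]
        if term in self.zeta_names:
            return self.zeta[:, self.zeta_names.index(term)]
        raise KeyError(f"{term!r} is not a selection (beta/zeta) term")

    @property
    def intercept(self) -> np.ndarray:
        if "intercept" in self.gamma_names:
            return self.gamma[:, self.gamma_names.index("intercept")]
        return np.zeros(self.n_retained)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        draws = pd.DataFrame(
            np.hstack([self.beta, self.zeta, self.gamma]),
            columns=self.beta_names + self.zeta_names + self.gamma_names,
        )
        for name, arr in (
            ("sigma2", self.sigma2), ("alpha1", self.alpha1), ("alpha2", self.alpha2),
            ("pi0_main", self.pi0_main), ("pi0_inter", self.pi0_inter),
            ("k_main", self.k_main), ("k_inter", self.k_inter),
        ):
            draws[f"__{name}"] = arr
        draws.to_csv(path / "draws.csv", index=False)
        meta = {
            "outcome": self.outcome,
            "seed": self.config.seed,
            "config": {k: v for k, v in self.config.__dict__.items()},
            "n_retained": self.n_retained,
            "y_center": self.y_center,
            "y_scale": self.y_scale,
            "beta_names": self.beta_names,
            "zeta_names": self.zeta_names,
            "gamma_names": self.gamma_names,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1, default=str))


def _check_block(mat: np.ndarray, names: list[str], label: str) -> None:
    if not np.all(np.isfinite(mat)):
        bad = int(np.where(~np.isfinite(mat).all(axis=0))[0][0])
        raise ValueError(f"non-finite values in {label} column {names[bad]!r}")
    if mat.shape[1]:
        norms = (mat**2).sum(axis=0)
        if (norms == 0).any():
            bad = int(np.where(norms == 0)[0][0])
            raise ValueError(f"degenerate (all-zero) {label} column {names[bad]!r}")


def npb_fit(design: DesignMatrices, config: NPBConfig) -> NPBChain:
    """Run the Gibbs sampler; reproducible given config.seed."""
    if design.n < 10:
        raise ValueError("need n >= 10 observations")
    if config.n_retained < 100:
        raise ValueError(
            f"chain would retain only {config.n_retained} draws; need >= 100"
        )
    y = np.asarray(design.y, dtype=float)
    xm = np.asfortranarray(design.x.to_numpy(dtype=float))
    zm = np.asfortranarray(design.z.to_numpy(dtype=float))
    wm = design.w.to_numpy(dtype=float) if design.w.shape[1] else np.zeros((design.n, 0))
    _check_block(xm, list(design.x.columns), "X")
    _check_block(zm, list(design.z.columns), "Z")
    _check_block(wm, list(design.w.columns), "W")
    n, p = xm.shape
    q = zm.shape[1]
    r = wm.shape[1]

    if config.standardize_outcome:
        y_center = float(y.mean())
        y_scale = float(y.std(ddof=1))
        if y_scale == 0:
            raise ValueError("outcome is constant")
    else:
        y_center, y_scale = 0.0, 1.0
    ys = (y - y_center) / y_scale

    rng = np.random.default_rng(config.seed)
    tau2 = config.slab_sd**2
    a_pi, b_pi = config.spike_weight_prior
    a_sig, b_sig = config.sigma2_prior
    c2 = config.covariate_prior_sd**2

    sigma2 = config.fix_sigma2 if config.fix_sigma2 is not None else 1.0
    pi0 = [config.fix_pi0 if config.fix_pi0 is not None else 0.5] * 2
    alpha = [config.a1 / config.b1, config.a2 / config.b2]

    blocks = []
    for mat in (xm, zm):
        pb = mat.shape[1]
        blocks.append(
            {
                "x": mat,
                "g": (mat**2).sum(axis=0),
                "assign": np.zeros(pb, dtype=np.int64),
                "atoms": np.zeros(pb + 2),
                "counts": np.concatenate([[pb], np.zeros(pb + 1)]).astype(np.int64),
                "n_clusters": 1,
                "coef": np.zeros(pb),  # independent mode only
            }
        )

    gamma = np.zeros(r)
    if r:
        wtw = wm.T @ wm
        prior_prec = np.eye(r) / c2
    e = ys.copy()

    T = config.n_retained
    out = {
        "beta": np.zeros((T, p)), "zeta": np.zeros((T, q)), "gamma": np.zeros((T, r)),
        "sigma2": np.zeros(T), "alpha1": np.zeros(T), "alpha2": np.zeros(T),
        "pi0_main": np.zeros(T), "pi0_inter": np.zeros(T),
        "k_main": np.zeros(T, dtype=int), "k_inter": np.zeros(T, dtype=int),
    }
    t = 0
    for it in range(config.n_iter):
        for b, blk in enumerate(blocks):
            if blk["x"].shape[1] == 0:
                continue
            if config.mode == "npb":
                blk["n_clusters"] = update_block_dp(
                    blk["x"], blk["g"], e, blk["assign"], blk["atoms"],
                    blk["counts"], blk["n_clusters"], sigma2, tau2,
                    pi0[b], alpha[b], rng,
                )
                update_atoms(
                    blk["x"], e, blk["assign"], blk["atoms"], blk["n_clusters"],
                    sigma2, tau2, rng,
                )
            else:
                update_block_independent(
                    blk["x"], blk["g"], e, blk["coef"], sigma2, tau2, pi0[b], rng
                )

        if r:
            resid_w = e + wm @ gamma
            prec = wtw / sigma2 + prior_prec
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, wm.T @ resid_w / sigma2)
            gamma_new = mean + np.linalg.solve(chol.T, rng.standard_normal(r))
            e = resid_w - wm @ gamma_new
            gamma = gamma_new

        if config.fix_sigma2 is None:
            rss = float(e @ e)
            sigma2 = 1.0 / rng.gamma(a_sig + 0.5 * n, 1.0 / (b_sig + 0.5 * rss))

        if config.mode == "npb":
            gammas = ((config.a1, config.b1), (config.a2, config.b2))
            for b, blk in enumerate(blocks):
                pb = blk["x"].shape[1]
                if pb == 0:
                    continue
                n_spike = int(blk["counts"][0])
                k_distinct = (1 if n_spike > 0 else 0) + blk["n_clusters"] - 1
                a_b, b_b = gammas[b]
                alpha[b] = _escobar_west(rng, alpha[b], pb, k_distinct, a_b, b_b)
                if config.fix_pi0 is None:
                    pi0[b] = rng.beta(a_pi + n_spike, b_pi + (pb - n_spike))
        elif config.fix_pi0 is None:
            for b, blk in enumerate(blocks):
                pb = blk["x"].shape[1]
                if pb == 0:
                    continue
                n_spike = int((blk["coef"] == 0.0).sum())
                pi0[b] = rng.beta(a_pi + n_spike, b_pi + (pb - n_spike))

        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0 and t < T:
            if config.mode == "npb":
                b0, b1_ = blocks
                out["beta"][t] = b0["atoms"][b0["assign"]]
                out["zeta"][t] = b1_["atoms"][b1_["assign"]]
                out["k_main"][t] = (1 if b0["counts"][0] > 0 else 0) + b0["n_clusters"] - 1
                out["k_inter"][t] = (1 if b1_["counts"][0] > 0 else 0) + b1_["n_clusters"] - 1
            else:
                out["beta"][t] = blocks[0]["coef"]
                out["zeta"][t] = blocks[1]["coef"]
                out["k_main"][t] = len(np.unique(blocks[0]["coef"]))
                out["k_inter"][t] = len(np.unique(blocks[1]["coef"]))
            out["gamma"][t] = gamma
            out["sigma2"][t] = sigma2
            out["alpha1"][t] = alpha[0]
            out["alpha2"][t] = alpha[1]
            out["pi0_main"][t] = pi0[0]
            out["pi0_inter"][t] = pi0[1]
            t += 1

    # back-transform to native outcome units (zeros stay exactly zero)
    gamma_native = out["gamma"] * y_scale
    gnames = list(design.w.columns)
    if "intercept" in gnames:
        gamma_native[:, gnames.index("intercept")] += y_center
    return NPBChain(
        beta=out["beta"] * y_scale,
        zeta=out["zeta"] * y_scale,
        gamma=gamma_native,
        sigma2=out["sigma2"] * y_scale**2,
        alpha1=out["alpha1"],
        alpha2=out["alpha2"],
        pi0_main=out["pi0_main"],
        pi0_inter=out["pi0_inter"],
        k_main=out["k_main"],
        k_inter=out["k_inter"],
        beta_names=list(design.x.columns),
        zeta_names=list(design.z.columns),
        gamma_names=gnames,
        outcome=design.outcome,
        config=config,
        y_center=y_center,
        y_scale=y_scale,
    )


def _escobar_west(rng, alpha, n, k, a, b):
    """Escobar & West (1995) auxiliary-variable update for a DP concentration."""
    eta = rng.beta(alpha + 1.0, n)
    rate = b - np.log(eta)
    odds = (a + k - 1.0) / (n * rate)
    if rng.random() < odds / (1.0 + odds):
        return rng.gamma(a + k, 1.0 / rate)
    return rng.gamma(a + k - 1.0, 1.0 / rate)


def exact_spike_slab_pip(
    x: np.ndarray, y: np.ndarray, sigma2: float, pi0: float, tau: float
) -> np.ndarray:
    """Exact PIPs for the independent spike-and-slab model by enumeration.

    Enumerates every zero/nonzero pattern over the selection columns; the
    nonzero coefficients are integrated out against N(0, tau^2) in closed
    form, so each pattern's weight is
    pi0^(#zeros) (1-pi0)^(#nonzeros) N(y | 0, sigma2 I + tau^2 X_S X_S').
    Feasible only for p <= 12 columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if p > 12:
        raise ValueError(f"enumeration over 2^{p} patterns refused (p <= 12)")
    tau2 = tau**2
    yy = float(y @ y)
    log_pi0, log_pi1 = np.log(pi0), np.log(1.0 - pi0)
    log_weights = np.empty(2**p)
    base = -0.5 * n * np.log(2.0 * np.pi * sigma2)
    for mask in range(2**p):
        idx = [j for j in range(p) if mask >> j & 1]
        k = len(idx)
        if k == 0:
            quad = yy / sigma2
            logdet = 0.0
        else:
            xs = x[:, idx]
            m = np.eye(k) + (tau2 / sigma2) * (xs.T @ xs)
            b = xs.T @ y
            sign, logdet = np.linalg.slogdet(m)
            quad = (yy - (tau2 / sigma2) * float(b @ np.linalg.solve(m, b))) / sigma2
        log_weights[mask] = (
            (p - k) * log_pi0 + k * log_pi1 + base - 0.5 * logdet - 0.5 * quad
        )
    log_weights -= log_weights.max()
    w = np.exp(log_weights)
    w /= w.sum()
    pip = np.zeros(p)
    for mask in range(2**p):
        for j in range(p):
            if mask >> j & 1:
                pip[j] += w[mask]
    return pip


def compute_pip(chain: NPBChain, term: str) -> float:
    """Fraction of retained draws in which the coefficient is exactly nonzero."""
    draws = chain.selection_draws(term)
    return float(np.mean(draws != 0.0))


PosteriorSummary = pd.DataFrame  # columns: block, mean, lo, hi, pip, units


def summarize_posterior(chain: NPBChain) -> PosteriorSummary:
    """Per-term posterior mean, equal-tailed 95% interval, and PIP.

    Means include the exact zeros (a model-averaged effect); intervals are
    the empirical 2.5%/97.5% quantiles. PIPs attach only to the selection
    (beta/zeta) terms. Effects are per 1 SD of each standardized exposure.
    """
    if chain.n_retained < 100:
        raise ValueError("need >= 100 retained draws to summarize")
    unit = "g" if chain.outcome == "birth_weight" else "% fat mass"
    rows = []
    for names, draws, block in (
        (chain.beta_names, chain.beta, "main"),
        (chain.zeta_names, chain.zeta, "interaction"),
        (chain.gamma_names, chain.gamma, "covariate"),
    ):
        for j, name in enumerate(names):
            d = draws[:, j]
            lo, hi = np.quantile(d, [0.025, 0.975])
            row = {
                "term": name,
                "block": block,
                "mean": float(d.mean()),
                "lo": float(lo),
                "hi": float(hi),
                "pip": float(np.mean(d != 0.0)) if block != "covariate" else np.nan,
            }
            if block == "main":
                row["units"] = f"{unit} per 1 SD"
            elif block == "interaction":
                row["units"] = f"{unit} per SD x SD"
            else:
                row["units"] = unit if name == "intercept" else f"{unit} per unit"
            rows.append(row)
    return pd.DataFrame(rows).set_index("term")


def selected_terms(summary: PosteriorSummary, threshold: float = 0.5) -> list[str]:
    """Terms with PIP strictly above the threshold."""
    sel = summary[summary["pip"] > threshold]
    return list(sel.index)


@dataclass
class SweepResult:
    grid: tuple[float, ...]
    selected: dict[float, list[str]]
    pips: pd.DataFrame  # selection terms x grid settings
    jaccard: pd.DataFrame


def sensitivity_sweep(
    design: DesignMatrices,
    base_config: NPBConfig,
    grid: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
    threshold: float = 0.5,
) -> SweepResult:
    """Refit with Gamma(g, g) concentration priors for each g in the grid.

    Reports the PIP table, each setting's selected-term set, and the
    pairwise Jaccard agreement of those sets (1.0 when both are empty).
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    selected: dict[float, list[str]] = {}
    pips = {}
    for gval in grid:
        cfg = replace(base_config, a1=gval, b1=gval, a2=gval, b2=gval)
        chain = npb_fit(design, cfg)
        summ = summarize_posterior(chain)
        sel_block = summ[summ["block"] != "covariate"]
        pips[gval] = sel_block["pip"]
        selected[gval] = selected_terms(sel_block, threshold)
    jac = pd.DataFrame(index=list(grid), columns=list(grid), dtype=float)
    for g1, g2 in combinations(list(grid), 2):
        s1, s2 = set(selected[g1]), set(selected[g2])
        jac.loc[g1, g2] = jac.loc[g2, g1] = (
            1.0 if not (s1 | s2) else len(s1 & s2) / len(s1 | s2)
        )
    for gval in grid:
        jac.loc[gval, gval] = 1.0
    return SweepResult(tuple(grid), selected, pd.DataFrame(pips), jac)


def convergence_report(
    chains: NPBChain | list[NPBChain], terms: list[str] | None = None
) -> pd.DataFrame:
    """ESS (and split-chain R-hat when >= 2 chains) for key scalars.

    Covers sigma^2, both concentration parameters, and the requested
    selection terms (default: all exposure main effects). A constant chain
    gets ESS at its floor of 1.0. Diagnostics via arviz.
    """
    import arviz as az

    if isinstance(chains, NPBChain):
        chains = [chains]
    if terms is None:
        terms = list(chains[0].beta_names)
    if chains[0].n_retained < 100:
        raise ValueError("need >= 100 retained draws")

    def stack(get):
        return np.stack([get(c) for c in chains])  # (n_chains, T)

    scalars = {"sigma2": stack(lambda c: c.sigma2),
               "alpha1": stack(lambda c: c.alpha1),
               "alpha2": stack(lambda c: c.alpha2)}
    for term in terms:
        scalars[term] = stack(lambda c, t=term: c.selection_draws(t))
    rows = []
    for name, draws in scalars.items():
        if np.ptp(draws) == 0.0:
            ess, rhat = 1.0, np.nan
        else:
            ess = float(az.ess(az.convert_to_dataset(draws))["x"])
            rhat = (
                float(az.rhat(az.convert_to_dataset(draws))["x"])
                if len(chains) >= 2
                else np.nan
            )
        total = draws.size
        rows.append(
            {
                "name": name,
                "ess": ess,
                "rhat": rhat,
                "n_draws": total,
                "flagged": bool(ess < 0.05 * total or (rhat == rhat and rhat > 1.1)),
            }
        )
    return pd.DataFrame(rows).set_index("name")
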