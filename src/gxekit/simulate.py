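"""Synthetic balanced genotype × environment × block data.

The generator draws from the split-plot model the analyses assume: an
observation of genotype g (enzyme) in environment e (temperature) and
block p is::

    y = mu + block_p + geno_g + env_e + gxe[g, e] + h_{e, p} + eps_{g, e, p}

with block_p ~ N(0, sigma_block^2), a main-plot error h shared by all
sub-plot observations of one (environment, block) pair — this shared draw
is what makes the split-plot error stratum estimable — and independent
sub-plot noise eps.  Effect vectors are centered and the interaction
matrix doubly centered, so the generating parameters line up one-to-one
with the terms the ANOVA estimates.

Default design: 4 genotypes × 5 environments × 6 complete blocks, the
layout of a multi-temperature enzyme-activity trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_CENTER_TOL = 1e-10


def _check_centered(v: np.ndarray, name: str) -> None:
    scale = max(float(np.abs(v).max(initial=0.0)), 1.0)
    if abs(float(v.sum(axis=0).max() if v.ndim == 1 else 0.0)) > _CENTER_TOL * scale:
        raise ValueError(f"{name} must sum to zero")
    if v.ndim == 2:
        if (np.abs(v.sum(axis=0)).max() > _CENTER_TOL * scale
                or np.abs(v.sum(axis=1)).max() > _CENTER_TOL * scale):
            raise ValueError(f"{name} must be doubly centered")


def contrast_basis(n: int, k: int) -> np.ndarray:
    """First k orthonormal centered polynomial contrasts of length n."""
    if not 1 <= k <= n - 1:
        raise ValueError(f"need 1 <= k <= n-1, got k={k}, n={n}")
    x = np.linspace(-1.0, 1.0, n)
    cols = np.column_stack([x**p for p in range(1, k + 1)])
    cols -= cols.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(cols)
    # fix QR sign indeterminacy: leading entry of each contrast negative
    # (ascending linear term)
    for j in range(k):
        if q[0, j] > 0:
            q[:, j] *= -1
    return q


def rank_k_interaction(g: int, e: int, magnitudes) -> np.ndarray:
    """Deterministic doubly-centered g × e interaction of rank len(magnitudes).

    Axis i is the outer product of the i-th genotype and environment
    polynomial contrasts scaled by ``magnitudes[i]``, so the matrix has
    sum of squares equal to ``sum(m**2 for m in magnitudes)``.
    """
    mags = np.asarray(magnitudes, float)
    k = len(mags)
    u = contrast_basis(g, k)
    v = contrast_basis(e, k)
    return (u * mags) @ v.T


@dataclass
class SimSpec:
    """Generating parameters for a balanced split-plot dataset.

    Parameters
    ----------
    g, e, r : int
        Numbers of genotypes, environments and complete blocks.
    mu : float
        Baseline activity level.
    genotype_effects, environment_effects : arrays or None
        Centered main-effect deviations (zero vectors if None).
    interaction : g × e array, sequence of axis magnitudes, or None
        Doubly-centered interaction matrix; a plain sequence of floats is
        expanded with :func:`rank_k_interaction`; None means no
        interaction.
    sigma_main : float
        Main-plot error SD (one draw per environment × block pair).
    sigma_sub : float
        Sub-plot (residual) error SD, one draw per observation.
    sigma_block : float
        SD of the random block effects.
    seed : int or None
        Default random seed used when :func:`simulate` gets none.
    """

    g: int = 4
    e: int = 5
    r: int = 6
    mu: float = 100.0
    genotype_effects: np.ndarray | None = None
    environment_effects: np.ndarray | None = None
    interaction: np.ndarray | None = None
    sigma_main: float = 0.5
    sigma_sub: float = 1.0
    sigma_block: float = 0.5
    seed: int | None = None
    genotype_labels: list = field(default=None, repr=False)
    environment_labels: list = field(default=None, repr=False)

    def __post_init__(self):
        if self.g < 1 or self.e < 1 or self.r < 1:
            raise ValueError("g, e and r must be positive")
        for name in ("sigma_main", "sigma_sub", "sigma_block"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.genotype_effects is None:
            self.genotype_effects = np.zeros(self.g)
        if self.environment_effects is None:
            self.environment_effects = np.zeros(self.e)
        self.genotype_effects = np.asarray(self.genotype_effects, float)
        self.environment_effects = np.asarray(self.environment_effects, float)
        if self.genotype_effects.shape != (self.g,):
            raise ValueError("genotype_effects must have length g")
        if self.environment_effects.shape != (self.e,):
            raise ValueError("environment_effects must have length e")
        if self.interaction is None:
            self.interaction = np.zeros((self.g, self.e))
        else:
            inter = np.asarray(self.interaction, float)
            if inter.ndim == 1:  # rank-k recipe: per-axis magnitudes
                inter = rank_k_interaction(self.g, self.e, inter)
            if inter.shape != (self.g, self.e):
                raise ValueError("interaction must be a g × e matrix")
            self.interaction = inter
        _check_centered(self.genotype_effects, "genotype_effects")
        _check_centered(self.environment_effects, "environment_effects")
        _check_centered(self.interaction, "interaction")
        if self.genotype_labels is None:
            self.genotype_labels = [f"G{i+1}" for i in range(self.g)]
        if self.environment_labels is None:
            self.environment_labels = [f"E{j+1}" for j in range(self.e)]


def simulate_values(spec: SimSpec, seed: int | None = None) -> np.ndarray:
    """Draw one dataset as an array ``y[g, e, r]`` (fast path)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    g, e, r = spec.g, spec.e, spec.r
    blocks = rng.normal(0.0, spec.sigma_block, r)
    h = rng.normal(0.0, spec.sigma_main, (e, r))
    eps = rng.normal(0.0, spec.sigma_sub, (g, e, r))
    y = (
        spec.mu
        + blocks[None, None, :]
        + spec.genotype_effects[:, None, None]
        + spec.environment_effects[None, :, None]
        + spec.interaction[:, :, None]
        + h[None, :, :]
        + eps
    )
    return y


def simulate(spec: SimSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one balanced long-format activity table.

    Identical spec and seed give bit-identical output.
    """
    y = simulate_values(spec, seed)
    g, e, r = spec.g, spec.e, spec.r
    gi, ei, ri = np.meshgrid(range(g), range(e), range(r), indexing="ij")
    return pd.DataFrame({
        "genotype": np.asarray(spec.genotype_labels, object)[gi.ravel()],
        "environment": np.asarray(spec.environment_labels, object)[ei.ravel()],
        "block": np.array([f"B{i+1}" for i in range(r)], object)[ri.ravel()],
        "value": y.ravel(),
    })


def expected_ammi_ss(spec: SimSpec) -> dict[str, float]:
    """Expected sums of squares of the pooled-error AMMI table.

    Closed forms under the generating model (noise inflations included):

    - genotype:     e*r*sum(rho^2) + (g-1)*sigma_sub^2
    - environment:  g*r*sum(psi^2) + (e-1)*(g*sigma_main^2 + sigma_sub^2)
    - interaction:  r*sum(gxe^2)   + (g-1)(e-1)*sigma_sub^2
    - error (blocks + both strata pooled):
      (r-1)*(g*e*sigma_block^2 + g*sigma_main^2 + sigma_sub^2)
      + (e-1)(r-1)*(g*sigma_main^2 + sigma_sub^2)
      + e*(r-1)(g-1)*sigma_sub^2
    """
    g, e, r = spec.g, spec.e, spec.r
    s2, sh2, sb2 = spec.sigma_sub**2, spec.sigma_main**2, spec.sigma_block**2
    whole = g * sh2 + s2
    ss = {
        "genotype": e * r * float((spec.genotype_effects**2).sum()) + (g - 1) * s2,
        "environment": g * r * float((spec.environment_effects**2).sum())
        + (e - 1) * whole,
        "interaction": r * float((spec.interaction**2).sum())
        + (g - 1) * (e - 1) * s2,
        "error": (r - 1) * (g * e * sb2 + whole)
        + (e - 1) * (r - 1) * whole
        + e * (r - 1) * (g - 1) * s2,
    }
    ss["total"] = sum(ss.values())
    return ss


def make_effects_for_target_ss(
    g: int,
    e: int,
    r: int,
    target_pcts: tuple[float, float, float],
    *,
    mu: float = 100.0,
    sigma_sub: float = 1.0,
    sigma_main: float = 0.5,
    sigma_block: float = 0.5,
    axis_shares: tuple[float, ...] = (0.9, 0.1),
    seed: int | None = None,
) -> SimSpec:
    """Inverse design: a spec whose expected SS shares hit given targets.

    Parameters
    ----------
    target_pcts : (genotype, environment, interaction) percentages
        Desired expected percent of total SS for the three systematic
        rows of the AMMI table (the remainder goes to pooled error).  An
        exactly-zero target requests no structural effect for that term.
    axis_shares : per-axis shares of the structural interaction SS
        Controls the rank and spectrum of the planted interaction.

    Returns
    -------
    SimSpec
        With polynomial-contrast effect patterns scaled so that, under
        the closed forms of :func:`expected_ammi_ss`, each expected share
        equals its target.

    Raises
    ------
    ValueError
        If the targets sum to >= 100 or a nonzero target is smaller than
        the share the noise alone already produces.
    """
    f = np.asarray(target_pcts, float) / 100.0
    if (f < 0).any() or f.sum() >= 1.0:
        raise ValueError("target percentages must be nonnegative and sum to < 100")
    s2, sh2, sb2 = sigma_sub**2, sigma_main**2, sigma_block**2
    whole = g * sh2 + s2
    e_err = ((r - 1) * (g * e * sb2 + whole)
             + (e - 1) * (r - 1) * whole
             + e * (r - 1) * (g - 1) * s2)
    total = e_err / (1.0 - f.sum())
    noise = np.array([(g - 1) * s2, (e - 1) * whole, (g - 1) * (e - 1) * s2])
    structural = f * total - noise
    for name, target, s in zip(("genotype", "environment", "interaction"),
                               f, structural):
        if target == 0:
            continue
        if s < 0:
            raise ValueError(
                f"infeasible {name} target: noise alone already exceeds "
                f"{100 * target:.4g}% of total SS"
            )
    structural = np.maximum(structural, 0.0)

    rho = contrast_basis(g, 1)[:, 0] * np.sqrt(structural[0] / (e * r))
    psi = contrast_basis(e, 1)[:, 0] * np.sqrt(structural[1] / (g * r))
    if structural[2] > 0:
        shares = np.asarray(axis_shares, float)
        if (shares < 0).any() or shares.sum() <= 0:
            raise ValueError("axis_shares must be nonnegative with positive sum")
        # a g × e table supports at most min(g-1, e-1) interaction axes
        shares = shares[: min(g - 1, e - 1)]
        shares = shares / shares.sum()
        mags = np.sqrt(structural[2] / r * shares)
        inter = rank_k_interaction(g, e, mags)
    else:
        inter = None
    return SimSpec(
        g=g, e=e, r=r, mu=mu,
        genotype_effects=rho, environment_effects=psi, interaction=inter,
        sigma_main=sigma_main, sigma_sub=sigma_sub, sigma_block=sigma_block,
        seed=seed,
    )
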