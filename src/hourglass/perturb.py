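"""Sensitivity analysis: per-division Gaussian perturbation of p and phi.

At every division event fresh parameter values are drawn: the threshold test
of each candidate cell uses phi' ~ Normal(phi, sigma_phi * phi) clipped below
at 0, and each executed division partitions with p' ~ Normal(p, sigma_p * p)
clipped to [0, 1].  A cell that fails its (noisy) threshold test is
permanently quiescent — it is never re-tested, matching the quiescence
framing of the unperturbed model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DEFAULT_CAPS, DivisionParams, GrowthCaps, LineageTree
from .rng import seed_sequence, substream
from .stochastic import _grow_tree, batch_final_stats

__all__ = ["PerturbationCurve", "grow_perturbed", "robustness_curve"]

_WHICH = {"p": (True, False), "phi": (False, True), "both": (True, True)}


def _check_sigma(name: str, value: float) -> float:
    if not (0.0 <= value <= 0.10):
        raise ValueError(
            f"{name} is a fraction of the mean in [0, 0.10], got {value!r}"
        )
    return float(value)


def grow_perturbed(
    params: DivisionParams,
    sigma_p: float,
    sigma_phi: float,
    n0: int,
    seed=None,
    caps: GrowthCaps = DEFAULT_CAPS,
) -> LineageTree:
    """Grow one lineage tree with per-division Gaussian parameter noise.

    With both sigmas zero no Gaussian draws are made, so the random stream
    coincides with grow_stochastic and matched seeds give identical trees.
    """
    return _grow_tree(
        params,
        n0,
        seed,
        caps,
        sigma_p=_check_sigma("sigma_p", sigma_p),
        sigma_phi=_check_sigma("sigma_phi", sigma_phi),
    )


@dataclass(frozen=True)
class PerturbationCurve:
    """Probability of hitting a target final size vs perturbation width.

    sigma_values are Gaussian standard deviations as fractions of the mean
    parameter (0 to 0.10); prob_target[k] is the fraction of replicates whose
    N_f equalled target_nf at sigma_values[k].
    """

    params: DivisionParams
    target_nf: int
    which: str
    n0: int
    reps: int
    sigma_values: tuple[float, ...]
    prob_target: tuple[float, ...]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sigma": self.sigma_values,
                "which": self.which,
                "prob_target": self.prob_target,
                "reps": self.reps,
            }
        )


def robustness_curve(
    params: DivisionParams,
    target_nf: int,
    sigma_axis,
    which: str = "both",
    n0: int = 10_000,
    reps: int = 1000,
    seed=None,
    caps: GrowthCaps = DEFAULT_CAPS,
) -> PerturbationCurve:
    """Fraction of replicates reaching target_nf at each perturbation width.

    which selects the perturbed parameter(s): "p", "phi" or "both".  Each
    sigma value runs on its own derived substream, so at sigma = 0 the curve
    reproduces the unperturbed confidence of target_nf up to binomial
    sampling error.
    """
    if which not in _WHICH:
        raise ValueError(f"which must be one of {sorted(_WHICH)}, got {which!r}")
    on_p, on_phi = _WHICH[which]
    sigmas = tuple(_check_sigma("sigma", s) for s in sigma_axis)
    root = seed_sequence(seed)
    probs = []
    for k, sigma in enumerate(sigmas):
        rng = np.random.default_rng(substream(root, k))
        sizes, _, _ = batch_final_stats(
            params,
            n0,
            reps,
            rng,
            caps,
            sigma_p=sigma if on_p else 0.0,
            sigma_phi=sigma if on_phi else 0.0,
        )
        probs.append(float((sizes == target_nf).mean()))
    return PerturbationCurve(
        params=params,
        target_nf=target_nf,
        which=which,
        n0=n0,
        reps=reps,
        sigma_values=sigmas,
        prob_target=tuple(probs),
    )
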