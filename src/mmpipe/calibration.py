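"""Monte-Carlo calibration of the hierarchical bootstrap.

Generates two-level null and effect datasets (site effects of SD ``tau``
around zero, neuron noise of SD ``sigma``) and measures rejection rates of
the hierarchical test, alongside a flat neuron-level bootstrap that ignores
the site grouping.  The flat bootstrap is expected to inflate the type-I
error when site effects are present — the reason the hierarchy matters.
"""

from __future__ import annotations

import numpy as np

from .hierboot import GroupedSample, hboot_test

__all__ = [
    "simulate_grouped",
    "flat_boot_p",
    "flat_two_group_p",
    "rejection_rate",
    "calibration_table",
]


def simulate_grouped(n_sites: int, neurons_per_site: int, tau: float,
                     sigma: float, effect: float,
                     rng: np.random.Generator) -> GroupedSample:
    """One dataset: value = effect + site_effect (SD tau) + noise (SD sigma)."""
    site_fx = rng.normal(0.0, tau, size=n_sites)
    values = (effect + np.repeat(site_fx, neurons_per_site)
              + rng.normal(0.0, sigma, size=n_sites * neurons_per_site))
    return GroupedSample(values, np.repeat(np.arange(n_sites), neurons_per_site))


def flat_boot_p(values: np.ndarray, n_boot: int, seed: int) -> float:
    """Two-sided p from a flat (neuron-level) bootstrap of the mean
    against zero, ignoring the site structure; same tie convention as the
    hierarchical test."""
    rng = np.random.default_rng(seed)
    n = values.size
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    p_gt = np.mean(means <= 0)
    p_lt = np.mean(means >= 0)
    return float(min(1.0, 2.0 * min(p_gt, p_lt)))


def flat_two_group_p(a: np.ndarray, b: np.ndarray, n_boot: int,
                     seed: int) -> float:
    """Two-sided p for the mean difference from flat neuron-level bootstraps
    of both groups, ignoring the site structure."""
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    p_gt = np.mean(diffs <= 0)
    p_lt = np.mean(diffs >= 0)
    return float(min(1.0, 2.0 * min(p_gt, p_lt)))


def rejection_rate(tau: float, sigma: float = 1.0, effect: float = 0.0,
                   n_sites: int = 5, neurons_per_site: int = 40,
                   n_datasets: int = 1000, n_boot: int = 1000,
                   alpha: float = 0.05, seed: int = 0,
                   method: str = "hierarchical") -> float:
    """Fraction of simulated two-group comparisons rejected at ``alpha``
    (two-sided).

    Each comparison draws two independent datasets from the same two-level
    distribution; ``effect`` shifts group a only, so ``effect = 0`` measures
    the type-I error of the unpaired test.
    """
    rng = np.random.default_rng(seed)
    rejected = 0
    for i in range(n_datasets):
        a = simulate_grouped(n_sites, neurons_per_site, tau, sigma, effect, rng)
        b = simulate_grouped(n_sites, neurons_per_site, tau, sigma, 0.0, rng)
        if method == "hierarchical":
            p = hboot_test(a, b, direction="two_sided", n_boot=n_boot,
                           seed=seed + 1 + i).p_value
        elif method == "flat":
            p = flat_two_group_p(a.values, b.values, n_boot, seed + 1 + i)
        else:
            raise ValueError(f"unknown method {method!r}")
        rejected += p < alpha
    return rejected / n_datasets


def calibration_table(taus=(0.0, 0.5, 1.0), effects=(0.0, 0.25, 0.5, 1.0),
                      sigma: float = 1.0, n_sites: int = 5,
                      neurons_per_site: int = 40, n_datasets: int = 1000,
                      n_boot: int = 1000, alpha: float = 0.05,
                      seed: int = 0) -> dict:
    """Type-I error (effect 0) across site-effect strengths, flat-bootstrap
    comparison at the largest tau, and power across planted effects."""
    out = {"alpha": alpha, "n_sites": n_sites,
           "neurons_per_site": neurons_per_site, "n_datasets": n_datasets,
           "n_boot": n_boot, "type_one": {}, "power": {}}
    for k, tau in enumerate(taus):
        out["type_one"][f"tau_{tau:g}"] = rejection_rate(
            tau, sigma, 0.0, n_sites, neurons_per_site, n_datasets, n_boot,
            alpha, seed + 1000 * k)
    out["type_one_flat_tau_max"] = rejection_rate(
        max(taus), sigma, 0.0, n_sites, neurons_per_site, n_datasets, n_boot,
        alpha, seed + 7777, method="flat")
    for k, eff in enumerate(effects):
        if eff == 0.0:
            continue
        out["power"][f"effect_{eff:g}"] = rejection_rate(
            0.5, sigma, eff * sigma, n_sites, neurons_per_site,
            max(200, n_datasets // 5), n_boot, alpha, seed + 100 * k + 5)
    return out
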