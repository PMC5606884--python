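"""Diagnostic plots: fitted attack-rate curves and coefficient intervals."""

from __future__ import annotations

import numpy as np


def plot_attack_curves(results, rings=("Danaus", "Tirumala", "Euploea"), pp_grid=None, ax=None):
    """Fitted attack probability vs background PP per ring (model status).

    Expects a results object from an AttackRateModel fit whose design used
    terms pp, ring, status and the ring x pp interaction with Danaus/model
    references.
    """
    import matplotlib.pyplot as plt
    from scipy.special import expit

    if ax is None:
        _, ax = plt.subplots()
    if pp_grid is None:
        pp_grid = np.linspace(0.3, 0.8, 50)
    p = results.params
    for ring in rings:
        eta = p.get("Intercept", 0.0) + p.get("pp", 0.0) * pp_grid
        if ring != rings[0]:
            eta = eta + p.get(f"ring[{ring}]", 0.0) + p.get(f"ring[{ring}]:pp", 0.0) * pp_grid
        ax.plot(pp_grid, expit(eta), label=ring)
    ax.set_xlabel("background predation pressure")
    ax.set_ylabel("fitted attack probability")
    ax.legend()
    return ax


def plot_coefficients(results, terms=None, ax=None):
    """Point estimates with 95% Wald intervals."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ci = results.conf_int()
    terms = list(terms) if terms else list(results.params.index)
    y = np.arange(len(terms))
    est = results.params[terms]
    ax.errorbar(
        est,
        y,
        xerr=[est - ci.loc[terms, "lower"], ci.loc[terms, "upper"] - est],
        fmt="o",
        capsize=3,
    )
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(y, terms)
    ax.set_xlabel("coefficient (logit scale)")
    return ax
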