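"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's Newton kernel: free
concentrations are found by nested interval bisection on the monotone mass
balances, so solver results can be checked against an implementation that
shares no code path with them.
"""

from __future__ import annotations

import numpy as np
import pytest

from cuspec import (Component, SpeciesDef, build_model, bundled_model,
                    distribution)

# ---------------------------------------------------------------------------
# models


@pytest.fixture(scope="session")
def cu_tyr():
    return bundled_model("Cu_Tyr")


@pytest.fixture(scope="session")
def cu_tyr_totals():
    return {"Cu": 1e-3, "Tyr": 2e-3}


@pytest.fixture(scope="session")
def cu_tyr_diagram(cu_tyr, cu_tyr_totals):
    """The binary distribution at the published conditions, 0.01 pH grid."""
    return distribution(cu_tyr, cu_tyr_totals, 2.5, 11.0, 0.01, "Cu")


def make_ml_toy(log_beta: float = 3.0):
    """Minimal M + L = ML model (no protonation chemistry)."""
    return build_model(
        [Component("M", role="metal"), Component("L", role="ligand"),
         Component("H", role="proton")],
        [SpeciesDef("ML", {"M": 1, "L": 1}, log_beta)])


def make_hl_toy(log_k: float = 10.28):
    """Monoprotic ligand toy: only HL forms."""
    return build_model(
        [Component("L", role="ligand"), Component("H", role="proton")],
        [SpeciesDef("HL", {"L": 1, "H": 1}, log_k)])


# ---------------------------------------------------------------------------
# oracles


def _bisect(f, lo, hi, iters=60):
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if (f(mid) > 0) == (flo > 0):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def oracle_free_concentrations(model, totals, pH):
    """Free concentrations by nested bisection (<= 2 non-proton components).

    The mass balance of each component is strictly increasing in its own
    free concentration, so nested bisection on log10 f converges without
    any Jacobian.
    """
    h = 10.0 ** (-pH)
    comps = [c for c in model.component_ids
             if c != model.proton_id and totals.get(c, 0.0) > 0]
    assert len(comps) in (1, 2), "oracle only supports 1-2 components"

    def conc(species, free):
        c = 10.0 ** species.log_beta * h ** species.coeff(model.proton_id)
        for cid, f in free.items():
            c *= f ** species.coeff(cid)
        return c

    def balance(cid, free):
        return (free[cid]
                + sum(s.coeff(cid) * conc(s, free) for s in model.species)
                - totals[cid])

    if len(comps) == 1:
        a = comps[0]
        fa = _bisect(lambda u: balance(a, {a: 10.0 ** u}),
                     np.log10(totals[a]) - 30, np.log10(totals[a]))
        return {a: 10.0 ** fa}

    a, b = comps

    def inner_b(fa):
        ub = _bisect(lambda u: balance(b, {a: fa, b: 10.0 ** u}),
                     np.log10(totals[b]) - 30, np.log10(totals[b]))
        return 10.0 ** ub

    ua = _bisect(lambda u: balance(a, {a: 10.0 ** u, b: inner_b(10.0 ** u)}),
                 np.log10(totals[a]) - 30, np.log10(totals[a]))
    fa = 10.0 ** ua
    return {a: fa, b: inner_b(fa)}


def oracle_titration_ph(model, protocol, v_mL):
    """pH at one titrant volume by brute-force bisection on the proton balance."""
    totals = protocol.totals_at(v_mL)
    t_h = protocol.proton_total_at(v_mL)
    kw = 10.0 ** (-model.pKw)

    def g(ph):
        h = 10.0 ** (-ph)
        if any(v > 0 for v in totals.values()):
            free = oracle_free_concentrations(model, totals, ph)
        else:
            free = {}
        bound = 0.0
        for s in model.species:
            c = 10.0 ** s.log_beta * h ** s.coeff(model.proton_id)
            for cid, f in free.items():
                c *= f ** s.coeff(cid)
            bound += s.coeff(model.proton_id) * c
        return h - kw / h + bound - t_h

    return _bisect(g, 1.0, model.pKw - 1.0)
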