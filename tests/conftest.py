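"""Shared fixtures: calibrated synthetic models and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from sialoscreen import calibrate
from sialoscreen.profile_hmm import ProfileHMM
from sialoscreen import synthetic_data as synth

CAL_N = 500
CAL_SEED = 11


@pytest.fixture(scope="session")
def models() -> dict[str, ProfileHMM]:
    """The default synthetic model bundle, calibrated once per session."""
    bundle = synth.default_models(seed=7)
    for name in sorted(bundle):
        calibrate(bundle[name], n_random=CAL_N, seed=CAL_SEED)
    return bundle


def random_small_model(rng: np.random.Generator, length: int) -> ProfileHMM:
    """A fully random (but valid) profile for brute-force comparisons."""
    def dirich(n, size=None):
        return rng.dirichlet(np.ones(n), size=size)

    t3 = dirich(3, length)
    t2a = dirich(2, length)
    t2b = dirich(2, length)
    return ProfileHMM(
        name="rand",
        match_emissions=dirich(20, length),
        insert_emissions=dirich(20, length),
        transitions={"MM": t3[:, 0], "MI": t3[:, 1], "MD": t3[:, 2],
                     "IM": t2a[:, 0], "II": t2a[:, 1],
                     "DM": t2b[:, 0], "DD": t2b[:, 1]},
        background=dirich(20),
    )


def brute_force_viterbi(model: ProfileHMM, x: np.ndarray) -> float:
    """Exhaustive enumeration of every legal local path; max log-odds bits.

    Independent of the dynamic-programming implementation: walks the state
    graph recursively (entry into any match state, exit after any match
    state, flanks free).
    """
    L = model.length
    n = len(x)
    with np.errstate(divide="ignore"):
        lodM = np.log2(model.match_emissions) - np.log2(model.background)
        lodI = np.log2(model.insert_emissions) - np.log2(model.background)
        lt = {k: np.log2(v) for k, v in model.transitions.items()}
    entry = -math.log2(L)
    best = -np.inf

    def rec(state, k, i, score):
        # state at node k having consumed residues x[:i]
        nonlocal best
        if state == "M":
            best = max(best, score)  # exit allowed after any match emission
        if state == "M":
            if k < L:
                if i < n:
                    rec("M", k + 1, i + 1, score + lt["MM"][k - 1] + lodM[k, x[i]])
                    rec("I", k, i + 1, score + lt["MI"][k - 1] + lodI[k - 1, x[i]])
                rec("D", k + 1, i, score + lt["MD"][k - 1])
        elif state == "I":
            if i < n:
                rec("I", k, i + 1, score + lt["II"][k - 1] + lodI[k - 1, x[i]])
                rec("M", k + 1, i + 1, score + lt["IM"][k - 1] + lodM[k, x[i]])
        else:  # D
            if k < L:
                if i < n:
                    rec("M", k + 1, i + 1, score + lt["DM"][k - 1] + lodM[k, x[i]])
                rec("D", k + 1, i, score + lt["DD"][k - 1])

    for b in range(1, L + 1):
        for i in range(n):
            rec("M", b, i + 1, entry + lodM[b - 1, x[i]])
    return best


def exhaustive_cluster_oracle(loci_with_roles, required_roles, window):
    """All-intervals oracle for gene-cluster detection on small tables."""
    required = frozenset(required_roles)
    by_rep = {}
    for rep, idx, roles in loci_with_roles:
        by_rep.setdefault(rep, {})[idx] = frozenset(roles) & required

    def covers(rolemap, lo, hi):
        got = set()
        for idx, r in rolemap.items():
            if lo <= idx <= hi:
                got |= r
        return required <= got

    out = set()
    for rep, rolemap in by_rep.items():
        idxs = sorted(rolemap)
        if not idxs:
            continue
        for lo in idxs:
            for hi in idxs:
                if hi < lo or hi - lo + 1 > window or not covers(rolemap, lo, hi):
                    continue
                minimal = not any(
                    covers(rolemap, a, b)
                    for a, b in ((lo + 1, hi), (lo, hi - 1))
                    if a <= b and (a, b) != (lo, hi)
                )
                if minimal:
                    out.add((rep, lo, hi))
    return sorted(out)
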