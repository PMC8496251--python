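"""CAPE-style reparametrization of pairwise coefficients into directed
influences.

Combined Analysis of Pleiotropy and Epistasis (CAPE) takes the main-effect
and interaction coefficients of one marker pair fitted on (at least) two
traits and rewrites them as a pair of δ terms,

    [δ1, δ2]ᵀ = [[β1¹, β2¹], [β1², β2²]]⁻¹ · [β12¹, β12²]ᵀ,

which describe how each marker enhances or suppresses the activity of the
other, and then as marker-to-marker influence terms m12, m21 defined through

    δ1 = m12·(1 + δ2),   δ2 = m21·(1 + δ1).

Because the matrix inversion can blow small coefficients up, standard errors
of the regression coefficients are propagated through the map with a
second-order Taylor expansion, and p-values for the standardized influence
statistics come from permutation testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CapeResult",
    "reparameterize",
    "deltas_to_influence",
    "propagate_errors",
    "cape_from_pair_scan",
    "cape_statistics_from_pair_scan",
    "cape_pvalues",
]

#: β-matrix condition numbers above this flag the pair as degenerate
CONDITION_MAX = 1e8
#: |1 + δ| below this flags the influence transform as singular
DELTA_TOL = 1e-8


@dataclass
class CapeResult:
    """Per-pair directed influence coefficients with propagated variances."""

    table: pd.DataFrame
    # columns: marker1, marker2, delta1, delta2, m12, m21,
    #          var_m12, var_m21, stat12, stat21, degenerate

    def statistics(self, pooled: bool = True) -> np.ndarray:
        ok = self.table[~self.table["degenerate"]]
        s = np.concatenate([ok["stat12"].to_numpy(), ok["stat21"].to_numpy()])
        return s[np.isfinite(s)]


def reparameterize(
    beta_matrix: np.ndarray, beta_int: np.ndarray
) -> tuple[float, float] | None:
    """Solve the 2×2 δ system; None if the β matrix is ill-conditioned.

    ``beta_matrix`` rows are traits, columns markers: [[β1¹, β2¹],
    [β1², β2²]]; ``beta_int`` is (β12¹, β12²).
    """
    B = np.asarray(beta_matrix, float)
    b = np.asarray(beta_int, float).ravel()
    if B.shape != (2, 2) or b.shape != (2,):
        raise ValueError("beta_matrix must be 2×2 and beta_int length 2")
    if not np.isfinite(B).all() or not np.isfinite(b).all():
        return None
    if np.linalg.cond(B) > CONDITION_MAX:
        return None
    d1, d2 = np.linalg.solve(B, b)
    return float(d1), float(d2)


def deltas_to_influence(
    delta1: float, delta2: float
) -> tuple[float, float] | None:
    """Translate δ terms into influence terms; None near the singularity.

    m12 = δ1/(1+δ2), m21 = δ2/(1+δ1); undefined when either denominator is
    within tolerance of zero.
    """
    if abs(1.0 + delta2) < DELTA_TOL or abs(1.0 + delta1) < DELTA_TOL:
        return None
    return delta1 / (1.0 + delta2), delta2 / (1.0 + delta1)


def _influence_map(beta6: np.ndarray) -> np.ndarray:
    """(β1¹, β2¹, β12¹, β1², β2², β12²) → (m12, m21); NaN when degenerate."""
    B = np.array([[beta6[0], beta6[1]], [beta6[3], beta6[4]]])
    b = np.array([beta6[2], beta6[5]])
    d = reparameterize(B, b)
    if d is None:
        return np.array([np.nan, np.nan])
    m = deltas_to_influence(*d)
    if m is None:
        return np.array([np.nan, np.nan])
    return np.array(m)


def propagate_errors(
    cov_trait1: np.ndarray,
    cov_trait2: np.ndarray,
    beta_matrix: np.ndarray,
    beta_int: np.ndarray,
) -> tuple[float, float]:
    """Second-order Taylor variances of (m12, m21).

    ``cov_trait1``/``cov_trait2`` are the symmetric 3×3 covariance blocks of
    (β̂₁, β̂₂, β̂₁₂) from each trait's regression; the two regressions are
    treated as independent blocks.  Var[f] ≈ gᵀΣg + ½·tr((HΣ)²) with g and H
    the gradient and Hessian of the influence map at the fitted β.
    """
    for C in (cov_trait1, cov_trait2):
        C = np.asarray(C, float)
        if C.shape != (3, 3) or not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("covariance blocks must be symmetric 3×3")
        eig = np.linalg.eigvalsh((C + C.T) / 2)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError("covariance block is not positive semidefinite")
    B = np.asarray(beta_matrix, float)
    b = np.asarray(beta_int, float).ravel()
    beta6 = np.array([B[0, 0], B[0, 1], b[0], B[1, 0], B[1, 1], b[1]])
    Sigma = np.zeros((6, 6))
    Sigma[:3, :3] = np.asarray(cov_trait1, float)
    Sigma[3:, 3:] = np.asarray(cov_trait2, float)

    f0 = _influence_map(beta6)
    if not np.isfinite(f0).all():
        raise ValueError("degenerate β configuration; no propagated variance")

    steps = 1e-4 * np.maximum(np.abs(beta6), 0.05)
    grad = np.zeros((2, 6))
    hess = np.zeros((2, 6, 6))
    fp = np.empty((6, 2))
    fm = np.empty((6, 2))
    for k in range(6):
        e = np.zeros(6)
        e[k] = steps[k]
        fp[k] = _influence_map(beta6 + e)
        fm[k] = _influence_map(beta6 - e)
        grad[:, k] = (fp[k] - fm[k]) / (2 * steps[k])
        hess[:, k, k] = (fp[k] - 2 * f0 + fm[k]) / steps[k] ** 2
    for k in range(6):
        for l in range(k + 1, 6):
            ek = np.zeros(6); ek[k] = steps[k]
            el = np.zeros(6); el[l] = steps[l]
            fpp = _influence_map(beta6 + ek + el)
            fpm = _influence_map(beta6 + ek - el)
            fmp = _influence_map(beta6 - ek + el)
            fmm = _influence_map(beta6 - ek - el)
            mixed = (fpp - fpm - fmp + fmm) / (4 * steps[k] * steps[l])
            hess[:, k, l] = mixed
            hess[:, l, k] = mixed
    if not (np.isfinite(grad).all() and np.isfinite(hess).all()):
        raise ValueError("influence map not differentiable at this β")

    out = []
    for i in range(2):
        HS = hess[i] @ Sigma
        var = float(grad[i] @ Sigma @ grad[i] + 0.5 * np.trace(HS @ HS))
        out.append(max(var, 0.0))
    return out[0], out[1]


# --------------------------------------------------------------------------
# pipeline entry points

def cape_from_pair_scan(pair_result) -> CapeResult:
    """Reparametrize a two-trait pairwise scan into directed influences.

    Requires a :class:`kinscan.scans.PairScanResult` over exactly two
    traits.  Degenerate pairs (ill-conditioned β matrix, |1+δ| ≈ 0, or a
    flagged regression) are reported with the ``degenerate`` flag set rather
    than dropped.
    """
    table = pair_result.table
    traits = list(dict.fromkeys(table["trait"]))
    if len(traits) != 2:
        raise ValueError(
            f"CAPE requires exactly 2 traits, got {len(traits)}: {traits}"
        )
    t1 = table[table["trait"] == traits[0]].set_index(["marker1", "marker2"])
    t2 = table[table["trait"] == traits[1]].set_index(["marker1", "marker2"])
    rows = []
    for pair in t1.index:
        r1, r2 = t1.loc[pair], t2.loc[pair]
        degenerate = bool(r1["flagged"]) or bool(r2["flagged"])
        d1 = d2 = m12 = m21 = v12 = v21 = s12 = s21 = np.nan
        if not degenerate:
            B = np.array(
                [[r1["beta1"], r1["beta2"]], [r2["beta1"], r2["beta2"]]]
            )
            bint = np.array([r1["beta12"], r2["beta12"]])
            d = reparameterize(B, bint)
            m = deltas_to_influence(*d) if d is not None else None
            if d is None or m is None:
                degenerate = True
            else:
                d1, d2 = d
                m12, m21 = m
                blocks = pair_result.coef_cov.get(pair, {})
                C1, C2 = blocks.get(traits[0]), blocks.get(traits[1])
                if C1 is None or C2 is None:
                    degenerate = True
                else:
                    try:
                        v12, v21 = propagate_errors(C1, C2, B, bint)
                    except ValueError:
                        degenerate = True
                    else:
                        s12 = m12 / np.sqrt(v12) if v12 > 0 else np.nan
                        s21 = m21 / np.sqrt(v21) if v21 > 0 else np.nan
        rows.append(
            (pair[0], pair[1], d1, d2, m12, m21, v12, v21, s12, s21,
             degenerate)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "marker1", "marker2", "delta1", "delta2", "m12", "m21",
            "var_m12", "var_m21", "stat12", "stat21", "degenerate",
        ],
    )
    return CapeResult(out)


def cape_statistics_from_pair_scan(pair_result) -> np.ndarray:
    """Pooled standardized |m| statistics (both directions) from a pair scan."""
    return np.abs(cape_from_pair_scan(pair_result).statistics())


def cape_pvalues(result: CapeResult, null) -> CapeResult:
    """Attach empirical p-values per direction from a permutation null."""
    from .scans import empirical_p

    t = result.table
    p12 = np.full(len(t), np.nan)
    p21 = np.full(len(t), np.nan)
    ok12 = np.isfinite(t["stat12"].to_numpy())
    ok21 = np.isfinite(t["stat21"].to_numpy())
    if ok12.any():
        p12[ok12] = empirical_p(t["stat12"].to_numpy()[ok12], null)
    if ok21.any():
        p21[ok21] = empirical_p(t["stat21"].to_numpy()[ok21], null)
    t = t.assign(p12=p12, p21=p21)
    return CapeResult(t)
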