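"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through a different code path than
the package (explicit enumeration / textbook formulas), so agreement is
a meaningful check rather than a tautology.
"""
from __future__ import annotations

import math

import numpy as np


def oracle_classify(rec) -> tuple[str, str, object]:
    """Straightforward re-implementation of the mutation rule table.

    Returns (class, tier, driving term) as plain strings/tuples.
    """
    flag = rec.literature_flag.value
    if flag in ("membrane_localisation", "other_localisation"):
        return ("4", "na", None)
    if flag == "catalysis":
        return ("1a", "na", "catalysis")
    if not rec.has_structure:
        return ("not_modelled", "na", None)

    terms: list[tuple[str, object, float]] = []
    if rec.ddg_fold is not None:
        terms.append(("fold", None, rec.ddg_fold))
    for t in rec.interface_terms:
        terms.append((t.kind.value, t.partner, t.ddg))

    precedence = ["fold", "intra_domain", "inhibitory_segment", "inter_protein"]
    kind_to_class = {
        "fold": "3",
        "intra_domain": "1a",
        "inhibitory_segment": "1b",
        "inter_protein": "2",
    }

    # Dominant term by exhaustive comparison: scan magnitudes, break exact
    # ties by walking the precedence list.
    dominant = None
    if terms:
        best_mag = max(abs(t[2]) for t in terms)
        for kind in precedence:
            matching = [t for t in terms if t[0] == kind and abs(t[2]) == best_mag]
            if matching:
                dominant = matching[0]
                break

    if dominant is not None and abs(dominant[2]) > 0.8:
        tier = "high" if abs(dominant[2]) > 1.6 else "significant"
        return (kind_to_class[dominant[0]], tier, dominant)
    if rec.location.value == "core":
        return ("core_subthreshold", "ns", dominant)
    return ("5", "ns", dominant)


def assignment_as_tuple(asg) -> tuple[str, str, object]:
    driving = asg.driving_term
    if isinstance(driving, tuple):
        driving = (driving[0], driving[1], driving[2])
    return (asg.klass.value, asg.tier.value, driving)


def permutation_p_value(a, b, n_resamples: int = 100_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the Welch t statistic."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na = a.size
    pooled = np.concatenate([a, b])

    def welch_t(x, y, axis=-1):
        mx, my = x.mean(axis=axis), y.mean(axis=axis)
        vx, vy = x.var(axis=axis, ddof=1), y.var(axis=axis, ddof=1)
        return (mx - my) / np.sqrt(vx / x.shape[-1] + vy / y.shape[-1])

    t_obs = welch_t(a, b)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(pooled) for _ in range(n_resamples)])
    t_perm = welch_t(perms[:, :na], perms[:, na:])
    return float((np.sum(np.abs(t_perm) >= abs(t_obs)) + 1) / (n_resamples + 1))


def pearson_r_textbook(x, y) -> float:
    """Pearson correlation from the definitional sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def one_site_binding_complex(total_a: float, total_b: float, kd: float) -> float:
    """Closed-form equilibrium complex abundance for one-site binding:
    the physical root of C² − (A+B+Kd)·C + A·B = 0 (all in molecules;
    kd in molecules)."""
    s = total_a + total_b + kd
    return (s - math.sqrt(s * s - 4.0 * total_a * total_b)) / 2.0
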