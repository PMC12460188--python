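"""Surrogate ("fake dyad") coherence baseline and its subtraction.

Coherence in a hyperscanning cohort is driven partly by the shared task
schedule, which every subject experiences identically.  Pairing each subject
with opposite-scanner subjects who were *not* their real partner yields
surrogate dyads whose coherence reflects only the task structure; the mean
over a subject's surrogate partners is that subject's baseline per
condition and ROI.  Subtracting the (member-mean) baseline from each real
dyad's terms leaves the dyad-specific component.  Surrogate pairings never
combine two subjects from the same scanner, so scanner-specific effects
cannot leak into the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError

__all__ = [
    "SurrogatePlan",
    "make_surrogate_plan",
    "compute_baseline",
    "subtract_baseline",
]


@dataclass(frozen=True)
class SurrogatePlan:
    """Per-subject ordered lists of opposite-scanner surrogate partners."""

    partners: dict[str, tuple[str, ...]]
    n_permutations: int
    seed: int
    exhaustive: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": s, "permutation": i, "partner": p}
            for s, plist in self.partners.items()
            for i, p in enumerate(plist)
        ]
        return pd.DataFrame(rows, columns=["subject", "permutation", "partner"])


def make_surrogate_plan(
    manifest: pd.DataFrame,
    n_permutations: int | None = None,
    seed: int = 0,
) -> SurrogatePlan:
    """Build the surrogate-pairing plan from the dyad manifest.

    ``manifest`` columns: dyad, subject_a, subject_b, scanner_a, scanner_b.
    With scanner groups of size n, each subject has n - 1 admissible
    partners (opposite scanner, true partner excluded).  ``n_permutations``
    defaults to n - 1, the exhaustive and therefore seed-independent plan;
    asking for more is infeasible.
    """
    true_partner: dict[str, str] = {}
    group: dict[str, list[str]] = {}
    scanner_of: dict[str, str] = {}
    for _, row in manifest.iterrows():
        a, b = row["subject_a"], row["subject_b"]
        true_partner[a] = b
        true_partner[b] = a
        scanner_of[a] = row["scanner_a"]
        scanner_of[b] = row["scanner_b"]
        group.setdefault(row["scanner_a"], []).append(a)
        group.setdefault(row["scanner_b"], []).append(b)
    if len(group) != 2:
        raise ConfigError(f"expected exactly two scanners, got {sorted(group)}")
    (s1, g1), (s2, g2) = sorted(group.items())
    if len(g1) != len(g2) or len(g1) < 2:
        raise ConfigError("scanner groups must have equal size >= 2")
    n = len(g1)
    if n_permutations is None:
        n_permutations = n - 1
    if not 1 <= n_permutations <= n - 1:
        raise ConfigError(
            f"n_permutations must lie in [1, {n - 1}], got {n_permutations}"
        )
    exhaustive = n_permutations == n - 1
    rng = np.random.default_rng(seed)
    partners: dict[str, tuple[str, ...]] = {}
    for subj in [*g1, *g2]:
        opposite = g2 if scanner_of[subj] == s1 else g1
        pool = sorted(p for p in opposite if p != true_partner[subj])
        if exhaustive:
            chosen = pool
        else:
            chosen = list(rng.choice(pool, size=n_permutations, replace=False))
        partners[subj] = tuple(chosen)
    return SurrogatePlan(
        partners=partners,
        n_permutations=n_permutations,
        seed=seed,
        exhaustive=exhaustive,
    )


def compute_baseline(
    plan: SurrogatePlan, surrogate_terms: pd.DataFrame
) -> pd.DataFrame:
    """Average surrogate terms into subject-specific baselines.

    ``surrogate_terms`` columns: subject, partner, condition, roi, value —
    one extracted coherence term per surrogate pairing.  The baseline is the
    mean over each subject's planned partners; missing pairings are averaged
    over what is available, with the count recorded.
    """
    df = surrogate_terms.copy()
    keep = [
        p in plan.partners.get(s, ())
        for s, p in zip(df["subject"], df["partner"])
    ]
    df = df[np.asarray(keep, dtype=bool)]
    out = (
        df.groupby(["subject", "condition", "roi"], sort=True)["value"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "value", "count": "n_partners"})
    )
    out["stage"] = "baseline"
    return out


def subtract_baseline(
    raw_table: pd.DataFrame,
    baseline: pd.DataFrame,
    manifest: pd.DataFrame,
    strategy: str = "mean",
) -> pd.DataFrame:
    """Baseline-corrected table: raw minus the dyad's combined baseline.

    ``strategy`` picks the combination of the two members' subject baselines:
    "mean" (symmetric default), "subject-a" or "subject-b".  Cells whose
    baseline is unavailable come back masked.
    """
    if strategy not in ("mean", "subject-a", "subject-b"):
        raise ConfigError(f"unknown baseline strategy {strategy!r}")
    members = manifest.set_index("dyad")[["subject_a", "subject_b"]]
    base = baseline.set_index(["subject", "condition", "roi"])["value"]

    def dyad_baseline(dyad: str, cond: str, roi) -> float:
        a, b = members.loc[dyad, "subject_a"], members.loc[dyad, "subject_b"]
        va = base.get((a, cond, roi), np.nan)
        vb = base.get((b, cond, roi), np.nan)
        if strategy == "subject-a":
            return va
        if strategy == "subject-b":
            return vb
        return (va + vb) / 2.0

    out = raw_table.copy()
    bvals = np.array(
        [
            dyad_baseline(d, c, r)
            for d, c, r in zip(out["dyad"], out["condition"], out["roi"])
        ]
    )
    out["baseline"] = bvals
    out["value"] = out["value"] - bvals
    out["missing"] = out["value"].isna()
    out["stage"] = "corrected"
    return out
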