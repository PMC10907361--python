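"""Decomposition of thermophilisation into immigration and extirpation.

Between each pair of consecutive *sampled* years at a site, every
species either persisted, was added (immigrated), or was lost
(extirpated). Comparing mean thermal affinities between those groups —
added vs persisted, added vs lost, lost vs persisted — shows whether a
community warms because warm-affinity species arrive, because
cold-affinity species disappear, or both. Whether contrasts fall above
or below zero more often than chance is assessed with an exact one-sided
binomial test against p = 0.5.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import FateTransition

logger = logging.getLogger("thermoshift")

CONTRAST_NAMES = ("added_vs_persisted", "added_vs_lost", "lost_vs_persisted")


def _mean_sti(group: frozenset, sti: Mapping[str, float]) -> Optional[float]:
    values = [sti[s] for s in group if s in sti]
    return float(np.mean(values)) if values else None


def classify_fates(species_by_year: Mapping[int, Iterable[str]],
                   site_id: str = "",
                   sti: Optional[Mapping[str, float]] = None
                   ) -> list[FateTransition]:
    """Species fates between consecutive sampled years of one site.

    Gaps between sampled years are allowed (transitions connect
    consecutive *sampled* years and are not weighted by gap length).
    Years with an empty species set are skipped with a warning. When an
    STI lookup is supplied the three mean-STI contrasts are attached;
    a contrast is ``None`` unless both groups have at least one profiled
    member.
    """
    years = sorted(species_by_year)
    sets = {y: frozenset(species_by_year[y]) for y in years}
    for y in years:
        if not sets[y]:
            logger.warning("site %s year %s has an empty species set; "
                           "transitions through it are skipped", site_id, y)
    years = [y for y in years if sets[y]]
    out = []
    for y0, y1 in zip(years, years[1:]):
        s0, s1 = sets[y0], sets[y1]
        persisted = s0 & s1
        added = s1 - s0
        lost = s0 - s1
        tr = FateTransition(site_id, y0, y1, persisted, added, lost)
        if sti is not None:
            mp = _mean_sti(persisted, sti)
            ma = _mean_sti(added, sti)
            ml = _mean_sti(lost, sti)
            if ma is not None and mp is not None:
                tr.added_vs_persisted = ma - mp
            if ma is not None and ml is not None:
                tr.added_vs_lost = ma - ml
            if ml is not None and mp is not None:
                tr.lost_vs_persisted = ml - mp
        out.append(tr)
    return out


def fate_sti_contrasts(transitions: Iterable[FateTransition],
                       sti: Optional[Mapping[str, float]] = None
                       ) -> pd.DataFrame:
    """Per-site mean of each STI contrast across its transitions.

    A contrast enters a transition's record only when both of its groups
    are non-empty after dropping unprofiled species; the site-level value
    is the mean of the defined per-transition contrasts, absent (NaN)
    when never defined. Transitions that were classified without an STI
    lookup get their contrasts computed here.

    Returns one row per site with the three contrast columns.
    """
    per_site: dict[str, dict[str, list[float]]] = {}
    for tr in transitions:
        if sti is not None:
            mp = _mean_sti(tr.persisted, sti)
            ma = _mean_sti(tr.added, sti)
            ml = _mean_sti(tr.lost, sti)
            contrasts = {
                "added_vs_persisted":
                    ma - mp if ma is not None and mp is not None else None,
                "added_vs_lost":
                    ma - ml if ma is not None and ml is not None else None,
                "lost_vs_persisted":
                    ml - mp if ml is not None and mp is not None else None,
            }
        else:
            contrasts = {c: getattr(tr, c) for c in CONTRAST_NAMES}
        bucket = per_site.setdefault(tr.site_id, {c: [] for c in CONTRAST_NAMES})
        for c, v in contrasts.items():
            if v is not None:
                bucket[c].append(v)
    rows = []
    for site, bucket in per_site.items():
        row = {"site_id": site}
        for c in CONTRAST_NAMES:
            row[c] = float(np.mean(bucket[c])) if bucket[c] else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["site_id", *CONTRAST_NAMES])


def site_fate_contrasts(observations: pd.DataFrame,
                        sti: Mapping[str, float]) -> pd.DataFrame:
    """Fate contrasts per site straight from a long observation table.

    Samples within a year are pooled to the year's species set before
    classification.
    """
    rows = []
    for site, grp in observations.groupby("site_id"):
        by_year = {int(y): set(g["species"]) for y, g in grp.groupby("year")}
        transitions = classify_fates(by_year, site, sti)
        if transitions:
            rows.append(fate_sti_contrasts(transitions, sti))
    if not rows:
        return pd.DataFrame(columns=["site_id", *CONTRAST_NAMES])
    return pd.concat(rows, ignore_index=True)


def sign_binomial_test(values, direction: str = "above"
                       ) -> tuple[int, int, float]:
    """Exact one-sided binomial test on the sign of contrast values.

    Zeros are dropped (a zero is evidence for neither direction); with
    ``n`` nonzero values and ``k`` matching the direction, the p-value is
    the exact upper tail P(X >= k | n, 0.5). Returns (k, n, p); p is NaN
    when no nonzero value remains.
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr) & (arr != 0)]
    n = int(arr.size)
    if n == 0:
        return 0, 0, float("nan")
    k = int((arr > 0).sum() if direction == "above" else (arr < 0).sum())
    p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
    return k, n, float(p)


def fate_summary(contrasts: pd.DataFrame,
                 group_cols: Optional[list[str]] = None) -> pd.DataFrame:
    """Group-level sign tests of the per-site contrasts.

    For each group (or the whole table) and each contrast, reports the
    number of sites above and below zero and the one-sided binomial
    p-value in each direction.
    """
    def one(grp: pd.DataFrame, label: dict) -> list[dict]:
        out = []
        for c in CONTRAST_NAMES:
            vals = grp[c].dropna()
            for direction in ("above", "below"):
                k, n, p = sign_binomial_test(vals, direction)
                out.append({**label, "contrast": c, "direction": direction,
                            "k": k, "n": n, "p_value": p})
        return out

    rows: list[dict] = []
    if group_cols:
        for key, grp in contrasts.groupby(group_cols):
            key = key if isinstance(key, tuple) else (key,)
            rows.extend(one(grp, dict(zip(group_cols, key))))
    else:
        rows.extend(one(contrasts, {}))
    return pd.DataFrame(rows)
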