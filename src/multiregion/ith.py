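"""Intratumoral heterogeneity statistics over the presence matrix.

Mutations are categorized by how many of a case's regional biopsies carry
them: ``public`` (all regions), ``shared`` (more than one but not all) and
``private`` (exactly one). With three biopsies this is the 3/2/1 scheme.
The public fraction is the primary ITH summary: a low public fraction
means most mutations are regionally restricted, i.e. high heterogeneity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotyper import PresenceMatrix
from .variants import LOF_CONSEQUENCES, MutationCall

CATEGORIES = ("public", "shared", "private")

#: SNV consequence classes counted as nonsynonymous in the NS/S ratio.
NS_CLASSES = frozenset({"missense", "nonsense", "splicing"})


def classify_regional(present: Sequence[bool], evaluable: Sequence[bool] | None = None) -> str:
    """Category of one site from its per-region presence.

    Only evaluable regions (adequate depth) count toward the denominator,
    so a region that could not be assessed never turns a clonal mutation
    into an apparently "shared" one.
    """
    present = np.asarray(present, dtype=bool)
    if evaluable is None:
        evaluable = np.ones(len(present), dtype=bool)
    evaluable = np.asarray(evaluable, dtype=bool)
    # a called mutation in a low-depth region is still an observation
    effective = evaluable | present
    n_eval = int(effective.sum())
    n_present = int(present[effective].sum())
    if n_present == 0:
        raise ValueError("cannot categorize an all-absent presence row")
    if n_present == n_eval:
        return "public"
    if n_present == 1:
        return "private"
    return "shared"


def categorize_matrix(pm: PresenceMatrix) -> pd.Series:
    """Per-site category for every row of a presence matrix."""
    cats = [
        classify_regional(pm.present.iloc[i].to_numpy(), pm.evaluable.iloc[i].to_numpy())
        for i in range(pm.n_sites)
    ]
    return pd.Series(cats, index=pm.present.index, name="category")


@dataclass
class IthSummary:
    n_total: int
    n_public: int
    n_shared: int
    n_private: int
    fraction_public: float
    fraction_shared: float
    fraction_private: float
    per_region_counts: dict
    n_flagged_low_coverage: int = 0
    burden_per_mb: float | None = None
    ns_s_ratio: float | None = None

    def to_json(self, **extra) -> str:
        d = asdict(self) | extra
        return json.dumps(d, indent=2, sort_keys=True)


def ith_summary(
    pm: PresenceMatrix,
    calls: Iterable[MutationCall] | None = None,
    target_size_mb: float = 50.0,
) -> IthSummary:
    """Summarize regional categories, mutation burden and the NS/S ratio.

    ``calls`` (any iterable of calls for the case, one per distinct site is
    enough) is only needed for the burden and NS/S statistics.
    """
    cats = categorize_matrix(pm)
    n = len(cats)
    counts = cats.value_counts()
    n_pub = int(counts.get("public", 0))
    n_sha = int(counts.get("shared", 0))
    n_pri = int(counts.get("private", 0))
    per_region = {r: int(pm.present[r].sum()) for r in pm.regions}
    flagged = int((~pm.evaluable.all(axis=1)).sum())

    burden = ns_s = None
    if calls is not None:
        unique = {c.site: c for c in calls}
        burden = mutation_burden(len(unique), target_size_mb)
        ns_s = ns_s_ratio(unique.values())
    return IthSummary(
        n_total=n,
        n_public=n_pub,
        n_shared=n_sha,
        n_private=n_pri,
        fraction_public=n_pub / n,
        fraction_shared=n_sha / n,
        fraction_private=n_pri / n,
        per_region_counts=per_region,
        n_flagged_low_coverage=flagged,
        burden_per_mb=burden,
        ns_s_ratio=ns_s,
    )


def mutation_burden(n_exonic_mutations: int, target_size_mb: float = 50.0) -> float:
    """Exonic mutations per megabase of capture target."""
    if target_size_mb <= 0:
        raise ValueError("target size must be positive (Mb)")
    if n_exonic_mutations < 0:
        raise ValueError("mutation count must be nonnegative")
    return n_exonic_mutations / target_size_mb


def ns_s_ratio(calls: Iterable[MutationCall]) -> float | None:
    """Nonsynonymous-to-synonymous SNV ratio.

    Numerator: missense + nonsense + canonical-splice SNVs; denominator:
    synonymous SNVs. Indels are excluded from both sides. Returns None
    (undefined) when there is no synonymous SNV.
    """
    ns = s = 0
    for c in calls:
        if not c.is_snv:
            continue
        if c.consequence in NS_CLASSES:
            ns += 1
        elif c.consequence == "synonymous":
            s += 1
    if s == 0:
        return None
    return ns / s
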