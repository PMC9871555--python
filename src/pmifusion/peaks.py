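"""Fragment confirmation: peak tables -> catalog -> feature matrices.

Peaks from different samples are identified as the same polypeptide
fragment when their migration times deviate by less than a relative
tolerance (2% by default, the instrument-level identity criterion).
Clustering alone cannot separate everything, though: real organ catalogs
contain distinct fragments whose mean migrations sit well inside 2% of
each other (e.g. 28.80 vs 28.99 s in lung). Two further facts are
therefore exploited:

* **same-sample exclusion** — the instrument already resolved two peaks of
  one electropherogram as distinct, so peaks sharing a ``sample_id`` are
  never merged into one fragment;
* **mass agreement** — when linking per-organ fragments into one
  study-wide catalog, candidate links must also agree in molecular mass
  (cluster means within ``mass_tolerance``, 1% by default), which
  separates cross-organ near-coincidences in migration time.

Fragments that pass confirmation are numbered consecutively by ascending
mean migration time, and a fragment is kept for an organ only if at least
one post-mortem time point shows it in at least 5 of the 6 biological
replicates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import ORGANS

logger = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclass
class FragmentCatalog:
    """Empirical fragment catalog plus the peak -> fragment assignment.

    ``fragments`` has one row per confirmed fragment (``fragment_id``,
    ``mean_mass``, ``sd_mass``, ``mean_migration``, ``sd_migration``,
    ``organs`` as a semicolon-joined string, empty when no manifest was
    supplied). ``assignment`` maps the index of the peak table that was
    matched to a ``fragment_id`` (or -1 for unassigned peaks).
    """

    fragments: pd.DataFrame
    assignment: pd.Series
    tolerance: float

    def organs_of(self, fragment_id: int) -> frozenset:
        row = self.fragments.loc[self.fragments["fragment_id"] == fragment_id]
        if row.empty:
            raise KeyError(f"unknown fragment_id {fragment_id}")
        cell = row["organs"].iloc[0]
        return frozenset(cell.split(";")) if cell else frozenset()

    def fragments_for_organ(self, organ: str) -> list[int]:
        ids = [
            int(r.fragment_id)
            for r in self.fragments.itertuples()
            if organ in (r.organs.split(";") if r.organs else [])
        ]
        return sorted(ids)


@dataclass
class FeatureMatrix:
    """Samples x fragments peak-height table with PMI labels."""

    X: pd.DataFrame  # index: sample_id, columns: fragment_id
    y: pd.Series  # PMI day per sample
    meta: pd.DataFrame  # rat_id, organ, cohort per sample
    organ: str

    def subset(self, cohort: str) -> "FeatureMatrix":
        mask = self.meta["cohort"] == cohort
        return FeatureMatrix(self.X[mask], self.y[mask], self.meta[mask], self.organ)


class _Cluster:
    __slots__ = ("indices", "samples", "sum_t", "sum_m")

    def __init__(self) -> None:
        self.indices: list[int] = []
        self.samples: set = set()
        self.sum_t = 0.0
        self.sum_m = 0.0

    @property
    def mean_t(self) -> float:
        return self.sum_t / len(self.indices)

    @property
    def mean_m(self) -> float:
        return self.sum_m / len(self.indices)

    def add(self, idx: int, sample, t: float, m: float) -> None:
        self.indices.append(idx)
        self.samples.add(sample)
        self.sum_t += t
        self.sum_m += m


def _greedy_cluster(peaks: pd.DataFrame, tolerance: float) -> list[_Cluster]:
    """Greedy migration-time clustering with same-sample exclusion.

    Peaks are processed in ascending migration time; each joins the cluster
    whose running mean is nearest in relative deviation (provided the
    deviation is below tolerance and the cluster holds no peak of the same
    sample), otherwise it seeds a new cluster.
    """
    order = peaks.sort_values(
        ["migration_time_s", "sample_id"], kind="mergesort"
    ).index
    clusters: list[_Cluster] = []
    for idx in order:
        t = float(peaks.at[idx, "migration_time_s"])
        m = float(peaks.at[idx, "molecular_mass_kda"])
        sample = peaks.at[idx, "sample_id"]
        best = None
        best_dev = tolerance
        for cl in clusters:
            dev = abs(t - cl.mean_t) / cl.mean_t
            if dev < best_dev and sample not in cl.samples:
                best, best_dev = cl, dev
        if best is None:
            best = _Cluster()
            clusters.append(best)
        best.add(idx, sample, t, m)
    return clusters


def _link_across_organs(
    organ_clusters: list[tuple[str, _Cluster]], tolerance: float, mass_tolerance: float
) -> list[list[int]]:
    """Union-find linkage of per-organ clusters into study-wide fragments.

    Candidate links (migration deviation < tolerance on the pair mean AND
    mass deviation < mass_tolerance) are applied smallest migration
    deviation first; a merge is refused when it would place two clusters of
    the same organ into one fragment.
    """
    n = len(organ_clusters)
    pairs = []
    for i in range(n):
        oi, ci = organ_clusters[i]
        for j in range(i + 1, n):
            oj, cj = organ_clusters[j]
            if oi == oj:
                continue
            mid_t = 0.5 * (ci.mean_t + cj.mean_t)
            dev_t = abs(ci.mean_t - cj.mean_t) / mid_t
            if dev_t >= tolerance:
                continue
            mid_m = 0.5 * (ci.mean_m + cj.mean_m)
            dev_m = abs(ci.mean_m - cj.mean_m) / mid_m if mid_m > 0 else np.inf
            if dev_m >= mass_tolerance:
                continue
            pairs.append((dev_t, i, j))
    pairs.sort()

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    group_organs: dict[int, set] = {i: {organ_clusters[i][0]} for i in range(n)}
    for _, i, j in pairs:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if group_organs[ri] & group_organs[rj]:
            continue  # would merge two clusters of one organ
        parent[rj] = ri
        group_organs[ri] |= group_organs.pop(rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def match_fragments(
    peaks: pd.DataFrame,
    tolerance: float = 0.02,
    manifest: pd.DataFrame | None = None,
    mass_tolerance: float = 0.01,
) -> FragmentCatalog:
    """Cluster peaks into a confirmed-fragment catalog.

    With a ``manifest``, peaks are clustered per organ and the per-organ
    fragments linked into study-wide numbered fragments with organ
    memberships; without one, all peaks are clustered as a single pool.
    Fragment ids are 1..n by ascending mean migration time. A post-hoc
    soundness pass unassigns any peak whose relative deviation from its
    fragment's final mean migration reaches the tolerance.
    """
    if peaks.empty:
        raise ValueError("peak table is empty")
    if not 0 < tolerance < 0.1:
        raise ValueError("tolerance must be in (0, 0.1)")
    if (peaks["migration_time_s"] <= 0).any():
        raise ValueError("non-positive migration times in peak table")

    if manifest is None:
        organ_clusters = [("", cl) for cl in _greedy_cluster(peaks, tolerance)]
    else:
        sample_organ = manifest.set_index("sample_id")["organ"]
        organ_of_peak = peaks["sample_id"].map(sample_organ)
        organ_clusters = []
        for organ in [o for o in ORGANS if o in set(organ_of_peak)]:
            sub = peaks[organ_of_peak == organ]
            organ_clusters.extend(
                (organ, cl) for cl in _greedy_cluster(sub, tolerance)
            )
    groups = _link_across_organs(organ_clusters, tolerance, mass_tolerance)

    records = []
    for group in groups:
        idx = [i for g in group for i in organ_clusters[g][1].indices]
        organs = sorted(
            {organ_clusters[g][0] for g in group} - {""},
            key=lambda o: ORGANS.index(o),
        )
        t = peaks.loc[idx, "migration_time_s"]
        m = peaks.loc[idx, "molecular_mass_kda"]
        records.append(
            {
                "mean_mass": m.mean(),
                "sd_mass": m.std(ddof=1) if len(m) > 1 else 0.0,
                "mean_migration": t.mean(),
                "sd_migration": t.std(ddof=1) if len(t) > 1 else 0.0,
                "organs": ";".join(organs),
                "_indices": idx,
            }
        )
    records.sort(key=lambda r: r["mean_migration"])

    assignment = pd.Series(UNASSIGNED, index=peaks.index, dtype=int)
    rows = []
    for fid, rec in enumerate(records, start=1):
        idx = rec.pop("_indices")
        assignment.loc[idx] = fid
        rows.append({"fragment_id": fid, **rec})
    fragments = pd.DataFrame(
        rows,
        columns=["fragment_id", "mean_mass", "sd_mass", "mean_migration", "sd_migration", "organs"],
    )

    # soundness: no assigned peak may deviate >= tolerance from its final mean
    mean_by_id = fragments.set_index("fragment_id")["mean_migration"]
    assigned = assignment[assignment != UNASSIGNED]
    devs = (
        peaks.loc[assigned.index, "migration_time_s"].to_numpy()
        - mean_by_id.loc[assigned.to_numpy()].to_numpy()
    )
    rel = np.abs(devs) / mean_by_id.loc[assigned.to_numpy()].to_numpy()
    bad = assigned.index[rel >= tolerance]
    if len(bad):
        logger.warning(
            "%d peaks exceeded the matching tolerance after clustering and "
            "were unassigned",
            len(bad),
        )
        assignment.loc[bad] = UNASSIGNED
    return FragmentCatalog(fragments=fragments, assignment=assignment, tolerance=tolerance)


def filter_by_replicate_support(
    catalog: FragmentCatalog,
    peaks: pd.DataFrame,
    manifest: pd.DataFrame,
    min_support: int = 5,
    replicates: int = 6,
) -> FragmentCatalog:
    """Keep a fragment for an organ only with >= ``min_support`` replicate hits.

    Replicate groups are (organ, PMI day) sample sets of the training
    study; a fragment is retained for an organ iff at least one time point
    has assigned peaks in at least ``min_support`` of that group's
    replicates. Organs losing a fragment have those peaks unassigned;
    fragments losing every organ are dropped; surviving fragments are
    renumbered by ascending mean migration.
    """
    meta = manifest.set_index("sample_id")
    assigned = catalog.assignment != UNASSIGNED
    hits = pd.DataFrame(
        {
            "fragment_id": catalog.assignment[assigned],
            "sample_id": peaks.loc[assigned, "sample_id"],
        }
    )
    hits["organ"] = hits["sample_id"].map(meta["organ"])
    hits["pmi_day"] = hits["sample_id"].map(meta["pmi_day"])

    group_sizes = meta.groupby(["organ", "pmi_day"]).size()
    small = group_sizes[group_sizes < min_support]
    if len(small):
        warnings.warn(
            f"{len(small)} replicate groups smaller than min_support="
            f"{min_support} were skipped",
            UserWarning,
            stacklevel=2,
        )
        valid_groups = set(group_sizes[group_sizes >= min_support].index)
        hits = hits[
            [
                (o, d) in valid_groups
                for o, d in zip(hits["organ"], hits["pmi_day"])
            ]
        ]

    # samples (not peaks) per fragment x organ x day
    support = (
        hits.drop_duplicates(["fragment_id", "sample_id"])
        .groupby(["fragment_id", "organ", "pmi_day"])
        .size()
    )
    supported: dict[int, set] = {}
    for (fid, organ, _day), count in support.items():
        if count >= min_support:
            supported.setdefault(int(fid), set()).add(organ)

    keep_rows = []
    assignment = catalog.assignment.copy()
    peak_organ = peaks["sample_id"].map(meta["organ"])
    for row in catalog.fragments.itertuples():
        hit_organs = supported.get(int(row.fragment_id), set())
        if row.organs:
            old_organs = set(row.organs.split(";"))
            new_organs = old_organs & hit_organs
        else:  # catalog built without a manifest: organs come from the hits
            old_organs = set(
                peak_organ[catalog.assignment == row.fragment_id].dropna().unique()
            )
            new_organs = hit_organs
        lost = old_organs - new_organs
        if lost:
            drop = (assignment == row.fragment_id) & peak_organ.isin(lost)
            assignment.loc[drop[drop].index] = UNASSIGNED
        if new_organs:
            keep_rows.append((int(row.fragment_id), new_organs))
        else:
            assignment.loc[assignment == row.fragment_id] = UNASSIGNED

    keep_rows.sort(
        key=lambda kr: float(
            catalog.fragments.set_index("fragment_id").at[kr[0], "mean_migration"]
        )
    )
    old_frags = catalog.fragments.set_index("fragment_id")
    rows = []
    remap = {}
    for new_id, (old_id, organs) in enumerate(keep_rows, start=1):
        remap[old_id] = new_id
        src = old_frags.loc[old_id]
        rows.append(
            {
                "fragment_id": new_id,
                "mean_mass": src["mean_mass"],
                "sd_mass": src["sd_mass"],
                "mean_migration": src["mean_migration"],
                "sd_migration": src["sd_migration"],
                "organs": ";".join(sorted(organs, key=ORGANS.index)),
            }
        )
    assignment = assignment.map(lambda f: remap.get(f, UNASSIGNED)).astype(int)
    fragments = pd.DataFrame(
        rows,
        columns=["fragment_id", "mean_mass", "sd_mass", "mean_migration", "sd_migration", "organs"],
    )
    return FragmentCatalog(
        fragments=fragments, assignment=assignment, tolerance=catalog.tolerance
    )


def build_feature_matrix(
    catalog: FragmentCatalog,
    peaks: pd.DataFrame,
    manifest: pd.DataFrame,
    organ: str,
) -> FeatureMatrix:
    """One row per sample of ``organ``, one column per retained fragment.

    Cells hold the assigned peak height, 0 where the fragment was not
    detected; when two peaks of one sample map to the same fragment the
    taller is kept (logged).
    """
    if organ not in set(manifest["organ"]):
        raise ValueError(f"organ {organ!r} not present in manifest")
    cols = catalog.fragments_for_organ(organ)
    if not cols:
        raise ValueError(f"catalog retains no fragments for organ {organ!r}")
    sub_manifest = manifest[manifest["organ"] == organ]
    samples = sub_manifest["sample_id"].tolist()
    missing = set(samples) - set(peaks["sample_id"])
    if missing:
        raise ValueError(
            f"samples without any peak table: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )

    assigned = catalog.assignment != UNASSIGNED
    tall = pd.DataFrame(
        {
            "sample_id": peaks.loc[assigned, "sample_id"],
            "fragment_id": catalog.assignment[assigned],
            "peak_height": peaks.loc[assigned, "peak_height"],
        }
    )
    tall = tall[tall["sample_id"].isin(samples) & tall["fragment_id"].isin(cols)]
    dup = tall.duplicated(["sample_id", "fragment_id"], keep=False)
    if dup.any():
        logger.info(
            "%d duplicate peak->fragment assignments resolved by keeping the "
            "taller peak",
            int(dup.sum()) - tall[dup].groupby(["sample_id", "fragment_id"]).ngroups,
        )
    heights = tall.groupby(["sample_id", "fragment_id"])["peak_height"].max()
    X = heights.unstack(fill_value=0.0).reindex(
        index=samples, columns=cols, fill_value=0.0
    )
    X.index.name = "sample_id"
    meta = sub_manifest.set_index("sample_id")[["rat_id", "organ", "cohort"]].loc[samples]
    y = sub_manifest.set_index("sample_id")["pmi_day"].loc[samples]
    return FeatureMatrix(X=X, y=y, meta=meta, organ=organ)


def assign_to_catalog(
    catalog: FragmentCatalog,
    peaks: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
) -> pd.Series:
    """Assign new (e.g. external-cohort) peaks to an existing catalog.

    No new fragments are created at predict time: each peak goes to the
    nearest catalog fragment within the matching tolerance (restricted to
    fragments of the sample's organ when a manifest is given, and never
    reusing a fragment twice within one sample); peaks matching nothing
    are logged and left unassigned.
    """
    frags = catalog.fragments
    if frags.empty:
        raise ValueError("catalog has no fragments to assign against")
    sample_organ = (
        manifest.set_index("sample_id")["organ"] if manifest is not None else None
    )
    assignment = pd.Series(UNASSIGNED, index=peaks.index, dtype=int)
    n_dropped = 0
    for sample_id, group in peaks.groupby("sample_id", sort=False):
        organ = sample_organ.get(sample_id) if sample_organ is not None else None
        if organ is not None:
            eligible = frags[
                frags["organs"].str.split(";").map(lambda os: organ in os)
            ]
        else:
            eligible = frags
        used: set[int] = set()
        for idx in group.sort_values("migration_time_s").index:
            t = float(peaks.at[idx, "migration_time_s"])
            dev = (eligible["mean_migration"] - t).abs() / eligible["mean_migration"]
            ok = dev[(dev < catalog.tolerance) & ~eligible["fragment_id"].isin(used)]
            if ok.empty:
                n_dropped += 1
                continue
            fid = int(eligible.loc[ok.idxmin(), "fragment_id"])
            assignment.at[idx] = fid
            used.add(fid)
    if n_dropped:
        logger.info("%d peaks matched no catalog fragment and were dropped", n_dropped)
    return assignment


def organ_membership_summary(catalog) -> dict:
    """Per-organ totals, shared-by-k counts and organ-exclusive counts.

    Accepts a :class:`FragmentCatalog` or a list of reference fragments.
    """
    if isinstance(catalog, FragmentCatalog):
        organ_sets = [
            frozenset(r.organs.split(";")) if r.organs else frozenset()
            for r in catalog.fragments.itertuples()
        ]
    else:
        organ_sets = [frozenset(f.organs) for f in catalog]
    per_organ = {o: sum(o in s for s in organ_sets) for o in ORGANS}
    shared_by = {k: sum(len(s) == k for s in organ_sets) for k in (1, 2, 3, 4)}
    exclusive = {o: sum(s == {o} for s in organ_sets) for o in ORGANS}
    return {
        "total": len(organ_sets),
        "per_organ": per_organ,
        "shared_by": shared_by,
        "exclusive": exclusive,
    }


@dataclass
class Standardizer:
    """Train-fitted per-fragment z-scoring applied to all cohorts."""

    mean_: pd.Series = field(default=None)
    scale_: pd.Series = field(default=None)

    def fit(self, train: pd.DataFrame) -> "Standardizer":
        if train.empty:
            raise ValueError("training matrix is empty")
        self.mean_ = train.mean(axis=0)
        sd = train.std(axis=0, ddof=0)
        self.scale_ = sd.mask(sd == 0, 1.0)  # constant columns pass through centered
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X * self.scale_ + self.mean_


def standardize(
    train: FeatureMatrix, others: list[FeatureMatrix]
) -> tuple[FeatureMatrix, list[FeatureMatrix], Standardizer]:
    """Z-score all matrices with mean/SD estimated on the training rows only."""
    scaler = Standardizer().fit(train.X)
    train_t = FeatureMatrix(scaler.transform(train.X), train.y, train.meta, train.organ)
    others_t = [
        FeatureMatrix(scaler.transform(fm.X), fm.y, fm.meta, fm.organ) for fm in others
    ]
    return train_t, others_t, scaler
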