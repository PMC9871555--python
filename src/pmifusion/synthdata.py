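"""Synthetic lab-on-chip electropherogram cohorts.

Emulates the rat post-mortem degradation study design: four organs (lung,
liver, kidney, skeletal muscle) sampled at 14 fixed post-mortem intervals
(0-30 days), six rats per time point in the training study plus an external
validation cohort of two rats per time point. Each organ sample yields a
peak table — one row per detected polypeptide fragment with migration time
(s), molecular mass (kDa) and peak height (fluorescence units) — as the
instrument software would export it.

The degradation signal is generated from a reference catalog of 45
polypeptide fragments (masses 14-230 kDa, the kit's separation range), each
with a fragment- and organ-specific rise-then-decay height trajectory over
post-mortem time. Measurement realism is limited to what the downstream
analysis is sensitive to: multiplicative lognormal replicate noise,
relative migration-time jitter, mass jitter, and detection dropout below a
fluorescence threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

ORGANS = ("lung", "liver", "kidney", "muscle")

#: Sampling days of the degradation study.
DEFAULT_PMI_DAYS = (0, 1, 2, 3, 5, 7, 9, 12, 15, 18, 21, 24, 27, 30)

PEAK_COLUMNS = ["sample_id", "migration_time_s", "molecular_mass_kda", "peak_height"]
MANIFEST_COLUMNS = ["sample_id", "rat_id", "organ", "pmi_day", "cohort"]


@dataclass(frozen=True)
class ReferenceFragment:
    """One canonical polypeptide fragment of the reference catalog."""

    fragment_id: int
    mean_mass: float  # kDa
    sd_mass: float  # kDa
    mean_migration: float  # seconds
    sd_migration: float  # seconds
    organs: frozenset[str]

    def __post_init__(self) -> None:
        if self.fragment_id < 1:
            raise ValueError(f"fragment_id must be >= 1, got {self.fragment_id}")
        if not self.organs:
            raise ValueError(f"fragment {self.fragment_id}: organ set is empty")
        unknown = set(self.organs) - set(ORGANS)
        if unknown:
            raise ValueError(f"fragment {self.fragment_id}: unknown organs {unknown}")


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: which days, how many rats, which organs."""

    pmi_days: tuple[float, ...] = DEFAULT_PMI_DAYS
    rats_per_timepoint: int = 6
    organs: tuple[str, ...] = ORGANS
    external_rats_per_timepoint: int = 2

    def __post_init__(self) -> None:
        if not self.pmi_days or self.rats_per_timepoint < 1 or not self.organs:
            raise ValueError("study design must have >=1 day, rat and organ")
        if list(self.pmi_days) != sorted(set(self.pmi_days)):
            raise ValueError("pmi_days must be strictly increasing")

    @property
    def n_rats(self) -> int:
        return len(self.pmi_days) * self.rats_per_timepoint

    @property
    def n_samples(self) -> int:
        return self.n_rats * len(self.organs)


@dataclass(frozen=True)
class KineticsParams:
    """Degradation-trajectory and measurement-noise parameters.

    Per-fragment trajectories are rise-then-decay curves
    ``h(t) = A * exp(rise * (t - peak_day))`` for ``t < peak_day`` and
    ``A * exp(-decay * (t - peak_day))`` afterwards, with ``A``, ``peak_day``
    and the rates drawn per (fragment, organ) from the seeded ranges below.
    ``trajectory_seed`` fixes the biology and is shared between the training
    and external cohorts; ``seed`` drives measurement noise only.
    """

    baseline_range: tuple[float, float] = (100.0, 800.0)  # fluorescence units
    peak_day_range: tuple[float, float] = (0.0, 30.0)  # days
    rise_range: tuple[float, float] = (0.08, 0.35)  # per day
    decay_range: tuple[float, float] = (0.08, 0.35)  # per day
    noise_sigma: float = 0.45  # lognormal sigma of replicate noise
    jitter_sigma: float = 0.004  # relative migration-time jitter
    mass_jitter_sigma: float = 0.02  # relative molecular-mass jitter
    detection_threshold: float = 20.0  # fluorescence units
    organ_noise_multipliers: dict[str, float] = field(
        default_factory=lambda: {"lung": 1.25, "liver": 1.6, "kidney": 0.8, "muscle": 1.0}
    )
    trajectory_seed: int = 1234
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.jitter_sigma < 0 or self.mass_jitter_sigma < 0:
            raise ValueError("noise scales must be >= 0")
        if self.detection_threshold < 0:
            raise ValueError("detection threshold must be >= 0")
        if any(m <= 0 for m in self.organ_noise_multipliers.values()):
            raise ValueError("organ noise multipliers must be > 0")

    def zero_noise(self) -> "KineticsParams":
        """Variant with no replicate noise, no jitter and no dropout."""
        return replace(
            self,
            noise_sigma=0.0,
            jitter_sigma=0.0,
            mass_jitter_sigma=0.0,
            detection_threshold=0.0,
        )


def load_reference_catalog() -> list[ReferenceFragment]:
    """Load the packaged 45-fragment reference catalog.

    The catalog lists each fragment's mean/SD molecular mass (kDa), mean/SD
    migration time (s) and the organs in which it was detected; fragments
    are numbered 1..45 by ascending migration time.
    """
    try:
        path = resources.files("pmifusion.data").joinpath("reference_fragments.csv")
        table = pd.read_csv(path)
    except (FileNotFoundError, OSError) as exc:  # pragma: no cover
        raise RuntimeError("packaged reference fragment catalog is missing") from exc
    required = {"fragment_id", "mean_mass", "sd_mass", "mean_migration", "sd_migration", "organs"}
    if not required.issubset(table.columns):
        raise RuntimeError("reference fragment catalog is corrupt: missing columns")
    fragments = [
        ReferenceFragment(
            fragment_id=int(row.fragment_id),
            mean_mass=float(row.mean_mass),
            sd_mass=float(row.sd_mass),
            mean_migration=float(row.mean_migration),
            sd_migration=float(row.sd_migration),
            organs=frozenset(row.organs.split(";")),
        )
        for row in table.itertuples()
    ]
    ids = [f.fragment_id for f in fragments]
    if ids != sorted(set(ids)):
        raise RuntimeError("reference fragment catalog is corrupt: duplicate ids")
    migrations = [f.mean_migration for f in fragments]
    if migrations != sorted(migrations):
        raise RuntimeError("reference fragment catalog is corrupt: migration order")
    return fragments


def _trajectory_params(
    kinetics: KineticsParams, fragment_id: int, organ: str
) -> tuple[float, float, float, float]:
    """Deterministic per-(fragment, organ) trajectory draw."""
    organ_index = ORGANS.index(organ)
    rng = np.random.default_rng([kinetics.trajectory_seed, fragment_id, organ_index])
    lo, hi = kinetics.baseline_range
    baseline = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    peak_day = rng.uniform(*kinetics.peak_day_range)
    rise = rng.uniform(*kinetics.rise_range)
    decay = rng.uniform(*kinetics.decay_range)
    return baseline, peak_day, rise, decay


def trajectory_height(
    kinetics: KineticsParams, fragment_id: int, organ: str, day: float
) -> float:
    """Noise-free expected peak height of a fragment at a given PMI day."""
    baseline, peak_day, rise, decay = _trajectory_params(kinetics, fragment_id, organ)
    if day < peak_day:
        return baseline * math.exp(rise * (day - peak_day))
    return baseline * math.exp(-decay * (day - peak_day))


def simulate_cohort(
    design: StudyDesign,
    catalog: Sequence[ReferenceFragment],
    kinetics: KineticsParams,
    cohort: str = "train",
    rat_id_offset: int = 0,
    external: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort of per-sample peak tables.

    Returns ``(peaks, manifest)``: ``peaks`` has one row per detected peak
    (columns ``sample_id, migration_time_s, molecular_mass_kda,
    peak_height``), ``manifest`` one row per organ sample (columns
    ``sample_id, rat_id, organ, pmi_day, cohort``). A fragment is emitted
    only in organs of its catalog organ set, with height
    ``trajectory(day) * organ_multiplier-scaled lognormal noise``, and is
    dropped when the noisy height falls below the detection threshold.
    Identical inputs (including seeds) give identical output.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    if kinetics.jitter_sigma >= 0.01:
        warnings.warn(
            f"migration jitter sigma {kinetics.jitter_sigma} risks violating the "
            "2% fragment-matching tolerance",
            UserWarning,
            stacklevel=2,
        )
    rats_per_tp = (
        design.external_rats_per_timepoint if external else design.rats_per_timepoint
    )
    if rats_per_tp < 1:
        raise ValueError("cohort has no rats")
    rng = np.random.default_rng([kinetics.seed, 1 if external else 0])

    peak_rows: list[tuple[str, float, float, float]] = []
    manifest_rows: list[tuple[str, str, str, float, str]] = []
    rat_counter = rat_id_offset
    for day in design.pmi_days:
        for _ in range(rats_per_tp):
            rat_counter += 1
            rat_id = f"{cohort}_rat{rat_counter:04d}"
            for organ in design.organs:
                sample_id = f"{rat_id}_{organ}"
                manifest_rows.append((sample_id, rat_id, organ, day, cohort))
                mult = kinetics.organ_noise_multipliers.get(organ, 1.0)
                for frag in catalog:
                    if organ not in frag.organs:
                        continue
                    expected = trajectory_height(kinetics, frag.fragment_id, organ, day)
                    noise = rng.normal(0.0, 1.0)
                    height = expected * math.exp(kinetics.noise_sigma * mult * noise)
                    migration = frag.mean_migration * (
                        1.0 + kinetics.jitter_sigma * rng.normal(0.0, 1.0)
                    )
                    mass = frag.mean_mass * (
                        1.0 + kinetics.mass_jitter_sigma * rng.normal(0.0, 1.0)
                    )
                    if height < kinetics.detection_threshold:
                        continue
                    peak_rows.append((sample_id, migration, max(mass, 0.1), height))
    peaks = pd.DataFrame(peak_rows, columns=PEAK_COLUMNS)
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    return peaks, manifest


def simulate_study(
    design: StudyDesign, catalog: Sequence[ReferenceFragment], kinetics: KineticsParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate training + external cohorts sharing the same degradation biology.

    The external cohort reuses ``trajectory_seed`` (same underlying
    kinetics) with an independent measurement-noise stream.
    """
    peaks_tr, man_tr = simulate_cohort(design, catalog, kinetics, cohort="train")
    peaks_ex, man_ex = simulate_cohort(
        design, catalog, kinetics, cohort="external", external=True
    )
    peaks = pd.concat([peaks_tr, peaks_ex], ignore_index=True)
    manifest = pd.concat([man_tr, man_ex], ignore_index=True)
    return peaks, manifest


def split_cohort(
    manifest: pd.DataFrame, test_fraction: float, seed: int
) -> pd.Series:
    """Assign each training-cohort sample to ``train`` or ``internal_test``.

    The split is by rat — all organ samples of one rat land on the same
    side — stratified by PMI day as evenly as class sizes allow, with
    ``ceil(test_fraction * n_rats)`` test rats. Returns a Series indexed
    like ``manifest`` with values ``train`` / ``internal_test`` (rows of
    other cohorts keep their cohort label).
    """
    from sklearn.model_selection import train_test_split

    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    train_mask = manifest["cohort"] == "train"
    rats = manifest.loc[train_mask, ["rat_id", "pmi_day"]].drop_duplicates("rat_id")
    rats = rats.sort_values("rat_id").reset_index(drop=True)
    n_rats = len(rats)
    n_test = math.ceil(test_fraction * n_rats)
    if n_test < 1 or n_test >= n_rats:
        raise ValueError(
            f"test_fraction {test_fraction} leaves an empty train or test set "
            f"({n_rats} rats, {n_test} test)"
        )
    try:
        _, test_rats = train_test_split(
            rats["rat_id"],
            test_size=n_test,
            stratify=rats["pmi_day"],
            random_state=seed % (2**31),
        )
    except ValueError:
        warnings.warn(
            "PMI classes too small to stratify the rat split; falling back to "
            "an unstratified split",
            UserWarning,
            stacklevel=2,
        )
        _, test_rats = train_test_split(
            rats["rat_id"], test_size=n_test, random_state=seed % (2**31)
        )
    test_set = set(test_rats)
    labels = manifest["cohort"].copy()
    labels.loc[train_mask] = [
        "internal_test" if rid in test_set else "train"
        for rid in manifest.loc[train_mask, "rat_id"]
    ]
    return labels
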