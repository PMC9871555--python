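"""Replication studies on synthetic cohorts.

Self-contained routines that rerun the pipeline's headline comparisons on
freshly simulated cohorts: multi-organ soft voting versus the best single
organ, and greedy pruning of an ensemble containing a planted adversarial
member. Used by the examples and the repository's acceptance script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import fusion as fus
from . import peaks as pk
from . import synthdata as sd

__all__ = ["fusion_benchmark", "catalog_recovery", "default_study_matrices"]


def default_study_matrices(
    seed: int,
    design: sd.StudyDesign | None = None,
    kinetics: sd.KineticsParams | None = None,
    test_fraction: float = 0.3,
) -> dict[str, dict[str, pk.FeatureMatrix]]:
    """Simulate the default study and return standardized per-organ cohorts.

    Returns ``{organ: {"train": ..., "internal": ..., "external": ...}}``.
    """
    design = design or sd.StudyDesign()
    kinetics = dataclasses.replace(kinetics or sd.KineticsParams(), seed=seed)
    catalog_ref = sd.load_reference_catalog()
    peaks, manifest = sd.simulate_study(design, catalog_ref, kinetics)
    manifest = manifest.assign(cohort=sd.split_cohort(manifest, test_fraction, seed))
    study_mask = manifest["cohort"].isin(["train", "internal_test"])
    study_samples = set(manifest.loc[study_mask, "sample_id"])
    study_peaks = peaks[peaks["sample_id"].isin(study_samples)]
    catalog = pk.match_fragments(study_peaks, manifest=manifest[study_mask])
    catalog = pk.filter_by_replicate_support(catalog, study_peaks, manifest[study_mask])
    ext_peaks = peaks[~peaks["sample_id"].isin(study_samples)]
    ext_assignment = pk.assign_to_catalog(catalog, ext_peaks, manifest)
    catalog.assignment = pd.concat([catalog.assignment, ext_assignment]).reindex(
        peaks.index, fill_value=pk.UNASSIGNED
    )
    out: dict[str, dict[str, pk.FeatureMatrix]] = {}
    for organ in design.organs:
        fm = pk.build_feature_matrix(catalog, peaks, manifest, organ)
        train, (internal, external), _ = pk.standardize(
            fm.subset("train"), [fm.subset("internal_test"), fm.subset("external")]
        )
        out[organ] = {"train": train, "internal": internal, "external": external}
    return out


def fusion_benchmark(seed: int) -> dict:
    """One seeded replicate of the multi-organ-versus-single-organ study.

    Fits a random-forest pipeline per organ on that organ's retained
    fragments, fuses the four class-probability vectors per rat by soft
    voting, and additionally prunes a five-member ensemble containing a
    planted adversarial member (confidently wrong by half the class
    range) on internal-validation accuracy.
    """
    data = default_study_matrices(seed)
    organs = list(data)
    classes = np.unique(data[organs[0]]["train"].y.to_numpy())

    pipes: dict[str, fus.FittedPipeline] = {}
    internal_probas: dict[str, np.ndarray] = {}
    external_acc: dict[str, float] = {}
    internal_acc: dict[str, float] = {}
    for organ in organs:
        train = data[organ]["train"]
        pipe = fus.FittedPipeline(
            organ, "RF", list(train.X.columns), seed=seed
        ).fit(train)
        pipes[organ] = pipe
        for cohort, store in (("internal", internal_acc), ("external", external_acc)):
            mat = data[organ][cohort]
            proba = pipe.predict_proba(mat, classes)
            pred = fus._argmax_earliest(proba, classes)
            store[organ] = float(np.mean(pred == mat.y.to_numpy()))
            if cohort == "internal":
                internal_probas[organ] = proba

    external_mats = {o: data[o]["external"] for o in organs}
    pred, _, _ = fus.fuse_organs(pipes, external_mats, "soft_voting", classes)
    y_ext = fus.align_by_rat(external_mats)[1].to_numpy()
    fused_external_acc = float(np.mean(pred == y_ext))

    # pruning study: a four-member ensemble where one member is
    # adversarial — three organ pipelines plus a member whose
    # probabilities are confidently anti-correlated with the truth
    internal_mats = {o: data[o]["internal"] for o in organs}
    rats, y_int = fus.align_by_rat(internal_mats)
    y_int = y_int.to_numpy()
    # the three comparably informative organs; the scenario deliberately
    # makes liver the weak view, which accuracy-greedy pruning would
    # legitimately remove
    good = [o for o in organs if o != "liver"]
    aligned_probas = {}
    for organ in good:
        mat = fus.reindex_by_rat(internal_mats[organ], rats)
        aligned_probas[organ] = pipes[organ].predict_proba(mat, classes)
    shift = len(classes) // 2
    wrong = (np.searchsorted(classes, y_int) + shift) % len(classes)
    aligned_probas["adversarial"] = np.eye(len(classes))[wrong]

    def _internal_accuracy(members: list[str]) -> float:
        vote, _ = fus.soft_vote([aligned_probas[m] for m in members], classes)
        return float(np.mean(vote == y_int))

    spec = fus.FusionSpec(members=sorted(aligned_probas), combiner="soft_voting")
    pruned, _ = fus.prune_ensemble(spec, _internal_accuracy)
    return {
        "external_accuracy": external_acc,
        "internal_accuracy": internal_acc,
        "fused_external_accuracy": fused_external_acc,
        "fusion_wins": fused_external_acc >= max(external_acc.values()),
        "pruned_members": sorted(pruned.active_members),
        "prune_exact": sorted(pruned.active_members) == sorted(good),
    }


def catalog_recovery(seed: int) -> dict:
    """Match a zero-jitter, zero-dropout cohort and compare with the
    reference catalog."""
    reference = sd.load_reference_catalog()
    kinetics = sd.KineticsParams(seed=seed).zero_noise()
    peaks, manifest = sd.simulate_cohort(sd.StudyDesign(), reference, kinetics)
    catalog = pk.match_fragments(peaks, manifest=manifest)
    recovered = [
        catalog.organs_of(fid) for fid in catalog.fragments["fragment_id"]
    ]
    expected = [frozenset(f.organs) for f in reference]
    matches = sum(
        int(len(recovered) > i and recovered[i] == expected[i])
        for i in range(len(expected))
    )
    return {
        "n_fragments": len(catalog.fragments),
        "organ_sets_matched": matches,
        "exact": len(catalog.fragments) == len(expected) and matches == len(expected),
    }
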