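"""End-to-end orchestration: synth -> features -> groups -> classify -> decode -> agree.

``run_pipeline`` executes every stage in dependency order on a synthetic (or
user-supplied) dataset, writes each stage's outputs with checksums, and
collates a deterministic summary.  One top-level seed derives per-stage
seeds, so any stage can be re-run reproducibly from cached upstream outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (accuracy_vs_chance_ttest, loo_cv,
                             permutation_null)
from .consistency import (AgreementResult, actual_agreement, agreement_test,
                          expected_agreement, subband_ttests)
from .features import FeatureSet, extract_features
from .grouping import PropertyGroups, form_groups, mean_ratings
from .neurodecoding import (group_level_map, roi_feature_matrix, searchlight,
                            _group_label_vector)
from .synthetic import (BetaSimulation, SyntheticConfig, default_config,
                        generate_ratings, generate_textures,
                        image_driving_statistics)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

CHANCE = 0.5


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    synth: SyntheticConfig = field(default_factory=default_config)
    fraction: float = 0.25
    families: Tuple[str, ...] = ("pixel", "spectral", "filter")
    n_perm: int = 500
    alpha: float = 0.05
    agreement_family: str = "spectral"
    searchlight_enabled: bool = False
    searchlight_radius: float = 4
    cluster_alpha: float = 0.001
    cluster_k: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.fraction <= 0.5:
            raise ValueError(f"fraction must be in (0, 0.5], got {self.fraction}")
        if self.n_perm < 100:
            raise ValueError(f"n_perm must be >= 100, got {self.n_perm}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        unknown = set(self.families) - {"pixel", "spectral", "filter"}
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        if self.agreement_family not in self.families:
            raise ValueError(
                f"agreement_family {self.agreement_family!r} not among "
                f"families {self.families}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = default_config(**raw.pop("synth", {}))
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(synth=synth, **raw)


def _stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (seed * 1000003 + stage * 7919 + 17) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Writes, under ``outdir``: ratings.csv, features_<family>.csv,
    groups_<property>.json, classify_<property>_<family>.json,
    mvpa_<property>.json, agreement_<property>.csv, summary.json and
    manifest.json.  ``summary.json`` is byte-identical across runs with the
    same config and seed.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package_version": __version__,
                      "numpy_version": np.__version__,
                      "seed": cfg.seed, "stages": {}, "outputs": {}}
    summary: dict = {"seed": cfg.seed, "properties": {}}
    written: List[Path] = []
    t_start = time.time()

    def stage_done(name: str, t0: float) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        logger.info("stage %s done in %.2fs", name, time.time() - t0)

    # ---------------------------------------------------------------- synth
    t0 = time.time()
    # the run seed owns all randomness: the synth block keeps its parameters
    # but its seed is derived from cfg.seed
    synth_cfg = replace(cfg.synth, seed=_stage_seed(cfg.seed, 0))
    images = generate_textures(synth_cfg)
    ids = synth_cfg.image_ids()
    ratings = generate_ratings(images, synth_cfg)
    ratings_path = outdir / "ratings.csv"
    ratings.to_csv(ratings_path, index=False)
    written.append(ratings_path)
    stage_done("synth", t0)

    # ------------------------------------------------------------- features
    t0 = time.time()
    features: Dict[str, FeatureSet] = {}
    for family in cfg.families:
        fs = extract_features(images, family, ids)
        features[family] = fs
        p = outdir / f"features_{family}.csv"
        fs.to_csv(p)
        written.append(p)
    stage_done("features", t0)

    # --------------------------------------------------------------- groups
    t0 = time.time()
    groups: Dict[str, PropertyGroups] = {}
    for prop in synth_cfg.properties:
        g = form_groups(mean_ratings(ratings, prop), cfg.fraction,
                        property=prop)
        groups[prop] = g
        p = outdir / f"groups_{prop}.json"
        g.to_json(p)
        written.append(p)
    stage_done("groups", t0)

    # ---------------------------------------------- image-statistics decode
    t0 = time.time()
    is_labels: Dict[str, Dict[str, pd.Series]] = {}
    for prop, g in groups.items():
        summary["properties"].setdefault(prop, {})
        prop_summary = summary["properties"][prop]
        prop_summary["image_classifier"] = {}
        is_labels[prop] = {}
        y = np.array([0] * g.n + [1] * g.n)
        for fi, family in enumerate(cfg.families):
            X = features[family].matrix.loc[g.all_ids].to_numpy()
            cv = loo_cv(X, y)
            pn = permutation_null(
                X, y, n_perm=cfg.n_perm, alpha=cfg.alpha,
                seed=_stage_seed(cfg.seed, 10 + fi))
            labels = pd.Series(
                np.where(cv.predicted == 1, "high", "low"), index=g.all_ids)
            is_labels[prop][family] = labels
            result = {
                "accuracy": cv.accuracy,
                "n_folds": cv.n_folds,
                "permutation_threshold": pn.threshold,
                "above_threshold": bool(cv.accuracy > pn.threshold),
                "labels": labels.to_dict(),
                "posterior": {i: float(p) for i, p in
                              zip(g.all_ids, cv.posterior)},
            }
            p = outdir / f"classify_{prop}_{family}.json"
            with open(p, "w") as fh:
                json.dump(result, fh, indent=2, sort_keys=True)
            written.append(p)
            prop_summary["image_classifier"][family] = {
                "accuracy": cv.accuracy,
                "permutation_threshold": pn.threshold,
                "above_threshold": bool(cv.accuracy > pn.threshold),
            }
        # per-subband contrasts for display
        if "spectral" in features:
            contrast = subband_ttests(features["spectral"], g)
            p = outdir / f"subband_t_{prop}.csv"
            contrast.t_values.to_csv(p)
            written.append(p)
    stage_done("image_classifier", t0)

    # -------------------------------------------------------------- betas
    t0 = time.time()
    stats = image_driving_statistics(images).set_axis(pd.Index(ids, name="image_id"))
    signal_cols = sorted({s for s in synth_cfg.coupling_dict.values()
                          if s is not None})
    signal = stats[signal_cols] if signal_cols else stats.iloc[:, :0]
    sim = BetaSimulation(signal, synth_cfg)
    stage_done("betas", t0)

    # ---------------------------------------------------------------- MVPA
    t0 = time.time()
    mvpa_labels: Dict[str, List[pd.Series]] = {p: [] for p in groups}
    roi_matrices = []
    for p_idx in range(synth_cfg.n_participants):
        betas = sim.participant_betas(p_idx)
        X_all, bids = roi_feature_matrix(betas, sim.roi_mask)
        roi_matrices.append((X_all, bids))
    for prop, g in groups.items():
        accs = []
        for p_idx, (X_all, bids) in enumerate(roi_matrices):
            idx, y = _group_label_vector(bids, g)
            cv = loo_cv(X_all[idx], y)
            accs.append(cv.accuracy)
            labels = pd.Series(np.where(cv.predicted == 1, "high", "low"),
                               index=[bids[j] for j in idx])
            mvpa_labels[prop].append(labels)
        tstat, pval = accuracy_vs_chance_ttest(accs)
        # permutation threshold per participant, then averaged across them
        thresholds = []
        for p_idx, (X_all, bids) in enumerate(roi_matrices):
            idx, y = _group_label_vector(bids, g)
            pn = permutation_null(
                X_all[idx], y, n_perm=cfg.n_perm, alpha=cfg.alpha,
                seed=_stage_seed(cfg.seed, 30 + p_idx))
            thresholds.append(pn.threshold)
        threshold = float(np.mean(thresholds))
        mv = {"per_participant_accuracy": accs,
              "mean_accuracy": float(np.mean(accs)),
              "t_vs_chance": tstat, "p_vs_chance": pval,
              "permutation_threshold": threshold,
              "above_threshold": bool(np.mean(accs) > threshold)}
        p = outdir / f"mvpa_{prop}.json"
        with open(p, "w") as fh:
            json.dump(mv, fh, indent=2, sort_keys=True)
        written.append(p)
        summary["properties"][prop]["mvpa"] = {
            "mean_accuracy": mv["mean_accuracy"],
            "p_vs_chance": pval,
            "above_threshold": mv["above_threshold"]}
    stage_done("mvpa", t0)

    # ---------------------------------------------------------- searchlight
    if cfg.searchlight_enabled:
        t0 = time.time()
        for prop, g in groups.items():
            maps = []
            for p_idx in range(synth_cfg.n_participants):
                betas = sim.participant_betas(p_idx)
                sl = searchlight(betas, sim.gm_mask, g,
                                 radius=cfg.searchlight_radius)
                maps.append(sl)
            grp = group_level_map(maps, alpha=cfg.cluster_alpha,
                                  cluster_k=cfg.cluster_k)
            p = outdir / f"searchlight_clusters_{prop}.csv"
            grp.clusters.to_csv(p, index=False)
            written.append(p)
            summary["properties"][prop]["searchlight"] = {
                "t_critical": grp.t_critical,
                "n_clusters": int(len(grp.clusters)),
            }
        stage_done("searchlight", t0)

    # ------------------------------------------------------------ agreement
    t0 = time.time()
    fam = cfg.agreement_family
    for prop, g in groups.items():
        results: List[AgreementResult] = []
        isl = is_labels[prop][fam]
        for p_idx, ml in enumerate(mvpa_labels[prop]):
            pid = sim.participant_ids()[p_idx]
            for pole, pole_ids in (("high", g.high_ids), ("low", g.low_ids)):
                la = isl.loc[pole_ids].to_numpy()
                lb = ml.reindex(pole_ids).to_numpy()
                a = float(np.sum(la == pole))
                b = float(np.sum(lb == pole))
                n = len(pole_ids)
                results.append(AgreementResult(
                    property=prop, pole=pole, participant_id=pid, n=n,
                    a=a, b=b, expected=expected_agreement(a, b, n),
                    actual=actual_agreement(la, lb)))
        df = pd.DataFrame([asdict_flat(r) for r in results])
        p = outdir / f"agreement_{prop}.csv"
        df.to_csv(p, index=False)
        written.append(p)
        test = agreement_test(results)
        summary["properties"][prop]["agreement"] = {
            k: {"t": v["t"], "p": v["p"], "mean_diff": v["mean_diff"]}
            for k, v in test.items()}
    stage_done("agreement", t0)

    # ------------------------------------------------------------- summary
    for prop in groups:
        s = summary["properties"][prop]
        fam_res = s["image_classifier"].get(fam, {})
        s["verdict"] = (
            "above threshold" if fam_res.get("above_threshold")
            else "at chance")
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    written.append(summary_path)

    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    manifest["total_seconds"] = round(time.time() - t_start, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def asdict_flat(obj) -> dict:
    """dataclass -> dict with tuples preserved (yaml/json friendly)."""
    return {k: v for k, v in asdict(obj).items()}
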