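"""End-to-end pipeline: preprocess -> align -> distance -> stats (+ IMS, Mantel).

``RunConfig`` holds every knob with the study's stated settings as defaults
(10 time points, 8 Hz cutoff, 1000 swap permutations, 5000 Mantel
permutations, 10-80% subsampling at 1000 iterations). ``run_pipeline``
writes every intermediate artifact to ``out_dir`` and a manifest listing
each file with its SHA-256 content hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .alignment import align_all_subjects
from .distance import pairwise_distances
from .ims import ims_distance, method_comparison
from .kinematics import build_trial_matrix
from .stats import mantel_test, mds_embed, robustness_subsample, swap_test
from .synth import DatasetDesign, generate_dataset

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("motordist")

CONFEDERATE_TAG = "confederate_instance"
PARTICIPANT_TAG = "participant"


@dataclass
class RunConfig:
    input_csv: str | None = None  # None -> simulate with `seed`
    out_dir: str = "motordist_out"
    sample_rate_hz: float = 100.0
    filter_cutoff_hz: float = 8.0
    n_timepoints: int = 10
    variable_set: tuple[str, ...] = ("wv", "wa", "wj")
    target_rule: str | int = "first_available"
    n_perm_swap: int = 1000
    n_perm_mantel: int = 5000
    subsample_fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    subsample_n_iter: int = 1000
    run_robustness: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("variable_set", "subsample_fractions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["variable_set"] = list(self.variable_set)
        d["subsample_fractions"] = list(self.subsample_fractions)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all artifacts.

    Returns a result bundle: per-condition distance matrices, swap-test and
    MDS results, IMS comparison, the cross-condition Mantel test when two
    conditions are present, and the artifact manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save(path: Path) -> Path:
        artifacts.append(path)
        return path

    if config.input_csv is not None:
        trials = mio.load_trials_csv(config.input_csv, sample_rate=config.sample_rate_hz)
        logger.info("loaded %d trials from %s", len(trials), config.input_csv)
    else:
        dataset = generate_dataset(DatasetDesign(sample_rate=config.sample_rate_hz), seed=config.seed)
        trials = dataset.raw_trials
        mio.write_trials_csv(trials, save(out / "trials.csv"))
        logger.info("simulated %d trials (seed %d)", len(trials), config.seed)

    matrices = [
        build_trial_matrix(
            tr,
            filter_cutoff=config.filter_cutoff_hz,
            n_timepoints=config.n_timepoints,
            variables=config.variable_set,
        )
        for tr in trials
    ]
    mio.write_trial_matrices_csv(matrices, save(out / "trial_matrices.csv"))

    conditions = sorted({tm.condition for tm in matrices})
    bundle: dict = {"config": config.to_dict(), "conditions": {}}
    dist_by_condition = {}
    for cond in conditions:
        cond_mats = [tm for tm in matrices if tm.condition == cond]
        fpts = align_all_subjects(cond_mats, target_rule=config.target_rule)
        logger.info("condition %s: %d FPT trials", cond, len(fpts))
        mio.write_fpts_csv(fpts, save(out / f"fpt_{cond}.csv"))

        D = pairwise_distances(fpts)
        dist_by_condition[cond] = D
        mio.write_distance_matrix(
            D, save(out / f"distance_{cond}.csv"), save(out / f"distance_{cond}.json")
        )

        cond_results: dict = {"n_subjects": D.n}
        groups = set(D.groups)
        if {CONFEDERATE_TAG, PARTICIPANT_TAG} <= groups:
            swap = swap_test(
                D,
                CONFEDERATE_TAG,
                PARTICIPANT_TAG,
                n_perm=config.n_perm_swap,
                seed=config.seed,
            )
            (save(out / f"swap_{cond}.json")).write_text(json.dumps(swap.to_dict(), indent=2))
            cond_results["swap_test"] = swap.to_dict()
            cond_results["conf_conf_mean"] = float(
                D.block_values(CONFEDERATE_TAG, CONFEDERATE_TAG).mean()
            )
            cond_results["conf_participant_mean"] = float(
                D.block_values(CONFEDERATE_TAG, PARTICIPANT_TAG).mean()
            )

            ims = ims_distance(fpts)
            comparison, delta = method_comparison(D, ims)
            mio.write_distance_matrix(
                ims.as_distance_matrix(),
                save(out / f"ims_{cond}.csv"),
                save(out / f"ims_{cond}.json"),
            )
            cmp_record = comparison.to_dict() | {
                "delta": delta,
                "ims_block_mean": comparison.observed_stat + delta,
            }
            (save(out / f"method_comparison_{cond}.json")).write_text(
                json.dumps(cmp_record, indent=2)
            )
            cond_results["ims_comparison"] = cmp_record

        emb = mds_embed(D)
        coords_rows = [
            {"subject": lab, "group": grp, "dim1": emb.coords[i, 0], "dim2": emb.coords[i, 1]}
            for i, (lab, grp) in enumerate(zip(D.labels, D.groups))
        ]
        pd.DataFrame(coords_rows).to_csv(save(out / f"mds_{cond}.csv"), index=False)
        (save(out / f"mds_{cond}.json")).write_text(
            json.dumps({"stress": emb.stress, "n_steps": emb.n_steps}, indent=2)
        )
        cond_results["mds"] = {"stress": emb.stress, "n_steps": emb.n_steps}

        if config.run_robustness:
            curve = robustness_subsample(
                cond_mats,
                fractions=config.subsample_fractions,
                n_iter=config.subsample_n_iter,
                seed=config.seed,
                target_rule=config.target_rule,
            )
            pd.DataFrame(
                {"fraction_removed": curve.fractions_removed, "icc": curve.icc}
            ).to_csv(save(out / f"robustness_{cond}.csv"), index=False)
            cond_results["robustness"] = dict(
                zip(curve.fractions_removed, curve.icc)
            )
        bundle["conditions"][cond] = cond_results

    if len(conditions) >= 2:
        c1, c2 = conditions[0], conditions[1]
        mantel = mantel_test(
            dist_by_condition[c1],
            dist_by_condition[c2],
            n_perm=config.n_perm_mantel,
            seed=config.seed,
        )
        (save(out / "mantel.json")).write_text(json.dumps(mantel.to_dict(), indent=2))
        bundle["mantel"] = mantel.to_dict()

    (out / "results.json").write_text(
        json.dumps(
            {k: v for k, v in bundle.items() if k != "manifest"},
            indent=2,
            default=float,
        )
    )
    artifacts.append(out / "results.json")
    manifest = {
        "seed": config.seed,
        "files": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    bundle["distance_matrices"] = dist_by_condition
    return bundle
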