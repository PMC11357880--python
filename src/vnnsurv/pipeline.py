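"""End-to-end orchestration with a digest-tracked run manifest.

A run executes the workflow stages in dependency order — simulate (or load
inputs), build the architecture, cross-validate/train, attribute, compute
impacts, stratify, subtype — writing each stage's artifacts into a run
directory.  Every artifact's SHA-256 digest is recorded in a manifest;
stages whose inputs and outputs are unchanged are skipped on re-runs, and
a corrupted intermediate file is reported by name instead of being
silently consumed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .architecture import build_vnn_spec
from .interpretation import feature_impact, shap_values
from .io_formats import (
    read_cohort,
    read_gene_sets,
    read_hierarchy,
    write_cohort,
    write_gene_sets,
    write_hierarchy,
    write_results,
)
from .model import (
    Hyperparams,
    cross_validate,
    default_grid,
    init_model,
    save_model,
    load_model,
    train,
)
from .stratification import assign_subtypes, make_gpi_result
from .synthetic import GroundTruth, simulate_cohort, simulate_hierarchy

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "RunManifest", "run_pipeline"]

STAGE_ORDER = [
    "simulate",
    "build_arch",
    "train",
    "explain",
    "impact",
    "stratify",
    "subtype",
]


class PipelineError(RuntimeError):
    pass


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of a pipeline run: config snapshot, per-stage seeds, input
    digests and output artifacts with digests."""

    config: dict
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # name -> {inputs, outputs, skipped}

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def load(cls, path: Path) -> "RunManifest | None":
        if not path.exists():
            return None
        data = json.loads(path.read_text())
        return cls(data["config"], data["seed"], data["version"], data["stages"])

    def verify(self) -> None:
        for stage, rec in self.stages.items():
            for f, dig in rec["outputs"].items():
                p = Path(f)
                if not p.exists() or _digest(p) != dig:
                    raise PipelineError(f"stage {stage}: output {f} missing or modified")


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config) -> RunManifest:
    """Execute the configured stages; returns the manifest (also written to
    ``<run_dir>/manifest.json``).

    Config keys: ``run_dir``, ``seed``, ``stages`` (subset of
    simulate/build_arch/train/explain/impact/stratify/subtype), plus
    per-stage sections; non-simulated inputs are given as ``cohort``,
    ``gmt`` and ``hierarchy`` paths.  Inputs are never mutated.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages") or ["build_arch", "train", "explain", "impact"]
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    stages = [s for s in STAGE_ORDER if s in stages]
    run_dir = Path(cfg.get("run_dir", "vnnsurv_run"))
    run_dir.mkdir(parents=True, exist_ok=True)

    manifest_path = run_dir / "manifest.json"
    previous = RunManifest.load(manifest_path)
    manifest = RunManifest(config=cfg, seed=seed, version=__version__)

    paths = {
        "cohort": cfg.get("cohort"),
        "gmt": cfg.get("gmt"),
        "hierarchy": cfg.get("hierarchy"),
    }

    def artifact(name: str) -> Path:
        return run_dir / name

    def up_to_date(stage: str, inputs: dict[str, str], outputs: list[Path]) -> bool:
        if previous is None or stage not in previous.stages:
            return False
        rec = previous.stages[stage]
        if rec["inputs"] != inputs:
            return False
        for f, dig in rec["outputs"].items():
            p = Path(f)
            if not p.exists():
                return False
            if _digest(p) != dig:
                raise PipelineError(
                    f"stage {stage}: recorded artifact {f} has been modified "
                    "(digest mismatch); remove it or the manifest to recompute"
                )
        return set(rec["outputs"]) == {str(o) for o in outputs}

    def record(stage: str, inputs: dict[str, str], outputs: list[Path], skipped: bool):
        manifest.stages[stage] = {
            "seed": _stage_seed(seed, stage),
            "inputs": inputs,
            "outputs": {str(o): _digest(o) for o in outputs},
            "skipped": skipped,
        }

    def input_digests(*files) -> dict[str, str]:
        out = {}
        for f in files:
            if f is None:
                continue
            p = Path(f)
            if not p.exists():
                raise PipelineError(f"missing upstream artifact: {f}")
            out[str(p)] = _digest(p)
        return out

    # -- simulate -------------------------------------------------------
    if "simulate" in stages:
        sim = cfg.get("simulate", {})
        outs = [artifact("cohort.tsv"), artifact("gene_sets.gmt"),
                artifact("hierarchy.tsv"), artifact("truth.tsv")]
        ins: dict[str, str] = {}
        if up_to_date("simulate", ins, outs):
            logger.info("simulate: up to date, skipping")
            record("simulate", ins, outs, skipped=True)
        else:
            s = _stage_seed(seed, "simulate")
            n_feat = int(sim.get("features", 20))
            gene_sets, hierarchy = simulate_hierarchy(
                int(sim.get("pathways", 12)), n_feat, int(sim.get("depth", 3)), seed=s
            )
            rng = np.random.default_rng(s)
            beta = np.zeros(n_feat)
            n_signal = int(sim.get("signal_features", 5))
            beta[:n_signal] = np.log(2) * np.where(
                np.arange(n_signal) % 2 == 0, 1.0, -1.0
            )
            truth = GroundTruth(
                true_beta=beta,
                feature_names=[f"G{i + 1:03d}" for i in range(n_feat)],
                clinical_beta=np.array([np.log(2), -np.log(2), -0.35]),
                baseline_hazard=1 / 2000.0,
                censor_rate_target=float(sim.get("censor_rate", 0.3)),
                seed=s,
                gene_sets=gene_sets,
                hierarchy=hierarchy,
            )
            cohort, truth = simulate_cohort(
                int(sim.get("n", 300)), np.full(n_feat, float(sim.get("freq", 0.3))),
                truth,
            )
            write_cohort(cohort, outs[0])
            write_gene_sets(gene_sets, outs[1])
            write_hierarchy(hierarchy, outs[2])
            pdtruth = truth.true_beta
            with open(outs[3], "w", encoding="utf-8") as fh:
                fh.write("feature\ttrue_beta\n")
                for fname, b in zip(truth.feature_names, pdtruth):
                    fh.write(f"{fname}\t{float(b)!r}\n")
            record("simulate", ins, outs, skipped=False)
        paths["cohort"], paths["gmt"], paths["hierarchy"] = map(str, outs[:3])

    cohort = None

    def get_cohort():
        nonlocal cohort
        if cohort is None:
            if paths["cohort"] is None:
                raise PipelineError("no cohort available: configure 'cohort' or the simulate stage")
            cohort = read_cohort(paths["cohort"])
        return cohort

    # -- build_arch -----------------------------------------------------
    spec_path = artifact("architecture.json")
    if "build_arch" in stages:
        ins = input_digests(paths["cohort"], paths["gmt"], paths["hierarchy"])
        outs = [spec_path]
        if up_to_date("build_arch", ins, outs):
            record("build_arch", ins, outs, skipped=True)
        else:
            co = get_cohort()
            spec = build_vnn_spec(
                read_gene_sets(paths["gmt"]), read_hierarchy(paths["hierarchy"]),
                co.feature_names,
                node_width=int(cfg.get("build_arch", {}).get("node_width", 1)),
            )
            spec_path.write_text(spec.to_json())
            record("build_arch", ins, outs, skipped=False)

    # -- train ----------------------------------------------------------
    model_path = artifact("model.json")
    cv_path = artifact("cv_report.tsv")
    if "train" in stages:
        ins = input_digests(paths["cohort"], spec_path)
        outs = [model_path, cv_path]
        if up_to_date("train", ins, outs):
            record("train", ins, outs, skipped=True)
        else:
            from .architecture import VNNSpec

            co = get_cohort()
            spec = VNNSpec.from_json(spec_path.read_text())
            tcfg = cfg.get("train", {})
            s = _stage_seed(seed, "train")
            grid = default_grid() if tcfg.get("grid", "default") == "default" else [
                Hyperparams(**g) for g in tcfg["grid"]
            ]
            head_width = int(tcfg.get("head_width", 16))
            report = cross_validate(
                co, spec, grid, k=int(tcfg.get("k", 5)), seed=s,
                head_width=head_width,
            )
            hp = report.chosen
            m0 = init_model(spec, co.n_clinical, head_width, hp.dropout_rate, seed=s)
            fitted, _ = train(m0, co, Hyperparams(
                learning_rate=hp.learning_rate, weight_decay=hp.weight_decay,
                batch_size=hp.batch_size, epochs=hp.epochs,
                dropout_rate=hp.dropout_rate, seed=s,
            ))
            save_model(fitted, model_path)
            with open(cv_path, "w", encoding="utf-8") as fh:
                fh.write("fold\tcindex\n")
                for i, sc in enumerate(report.fold_scores):
                    fh.write(f"{i}\t{float(sc)!r}\n")
            record("train", ins, outs, skipped=False)

    # -- explain --------------------------------------------------------
    shap_path = artifact("shap_inputs.tsv")
    if "explain" in stages:
        ins = input_digests(paths["cohort"], model_path)
        outs = [shap_path]
        if up_to_date("explain", ins, outs):
            record("explain", ins, outs, skipped=True)
        else:
            co = get_cohort()
            fitted = load_model(model_path)
            s = _stage_seed(seed, "explain")
            shap = shap_values(
                fitted, co, background="zeros", scope="inputs",
                method="sampling", seed=s, players=co.feature_names,
            )
            import pandas as pd

            df = pd.DataFrame(shap.values, columns=shap.node_names)
            df.insert(0, "patient_id", co.patient_id)
            df["base_value"] = shap.base_value
            df["risk"] = shap.risk
            df.to_csv(shap_path, sep="\t", index=False, float_format="%.17g")
            record("explain", ins, outs, skipped=False)

    # -- impact ---------------------------------------------------------
    impact_path = artifact("impact.tsv")
    if "impact" in stages:
        ins = input_digests(paths["cohort"], shap_path)
        outs = [impact_path]
        if up_to_date("impact", ins, outs):
            record("impact", ins, outs, skipped=True)
        else:
            import pandas as pd

            from .interpretation import ShapMatrix

            co = get_cohort()
            df = pd.read_csv(shap_path, sep="\t")
            names = [c for c in df.columns
                     if c not in ("patient_id", "base_value", "risk")]
            shap = ShapMatrix(
                df[names].to_numpy(float), names,
                df["base_value"].to_numpy(float), df["risk"].to_numpy(float),
                scope="inputs",
            )
            write_results(feature_impact(shap, co), impact_path)
            record("impact", ins, outs, skipped=False)

    # -- stratify -------------------------------------------------------
    gpi_path = artifact("gpi.tsv")
    if "stratify" in stages:
        scfg = cfg.get("stratify", {})
        ins = input_digests(paths["cohort"], impact_path)
        outs = [gpi_path]
        if up_to_date("stratify", ins, outs):
            record("stratify", ins, outs, skipped=True)
        else:
            from .io_formats import read_results

            co = get_cohort()
            impact = read_results(impact_path)
            f_key = scfg.get("f_key")
            if not f_key:
                ranked = sorted(
                    impact.feature,
                    key=lambda f: abs(impact.as_dict()[f]), reverse=True,
                )
                f_key = ranked[: int(scfg.get("top", 10))]
            gpi = make_gpi_result(
                co, impact, f_key,
                float(scfg.get("t1", -0.015)), float(scfg.get("t2", 0.025)),
            )
            write_results(gpi, gpi_path)
            record("stratify", ins, outs, skipped=False)

    # -- subtype --------------------------------------------------------
    subtype_path = artifact("subtypes.tsv")
    if "subtype" in stages:
        bcfg = cfg.get("subtype", {})
        if not bcfg.get("h1") or not bcfg.get("l1"):
            raise PipelineError("subtype stage requires 'h1' and 'l1' marker lists")
        ins = input_digests(paths["cohort"])
        outs = [subtype_path]
        if up_to_date("subtype", ins, outs):
            record("subtype", ins, outs, skipped=True)
        else:
            co = get_cohort()
            write_results(assign_subtypes(co, bcfg["h1"], bcfg["l1"]), subtype_path)
            record("subtype", ins, outs, skipped=False)

    manifest_path.write_text(manifest.to_json())
    return manifest
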