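"""End-to-end orchestration with a declarative config and a run manifest.

Stages: syndata (or load) -> qc -> dge -> markers -> identity -> dysreg.
All numeric outputs are serialized with 10 significant digits so reruns with
the same config and seed are byte-identical. One global seed is fanned out
to stage-local generators through stable stage labels, so adding a stage
does not perturb the draws of earlier stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dge as dge_mod
from . import dysreg as dysreg_mod
from . import identity as id_mod
from . import io as io_mod
from . import markers as mk_mod
from . import qc as qc_mod
from . import syndata
from .syndata import CANONICAL_SUBTYPES, SimConfig

log = logging.getLogger("spnblur")
FLOAT_FMT = "%.10g"


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """Stage-local generator derived from the global seed and a stable label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run.

    Exactly one of ``input`` (paths to matrix.mtx / cells.tsv / genes.tsv)
    and ``sim`` (a SimConfig) must be given.
    """

    sim: SimConfig | None = None
    input: dict | None = None
    species: str = "mouse"
    max_mito_frac: float | None = None
    min_unique_genes: int = 500
    lfc_min: float = 0.1
    alpha: float = 0.001
    strict_marker_lfc_min: float = 0.2
    use_adjusted_p: bool = True
    weights_mode: str = "none"
    log_base: float = 2.0
    normalization: str = "cpm_mean"
    min_detect_frac: float = 0.0
    regression_order: int = 1
    regression_ci: float = 0.99
    directionality_mode: str = "as-described"
    directionality_use_adjusted: bool = False
    gene_set: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if (self.sim is None) == (self.input is None):
            raise ValueError("exactly one of sim / input must be configured")
        for name in ("lfc_min", "alpha", "strict_marker_lfc_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sim is not None:
            self.sim.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("subtypes",):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.sim = SimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
            if isinstance(d["sim"].get("subtypes"), tuple):
                d["sim"]["subtypes"] = list(d["sim"]["subtypes"])
        return d


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None):
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT,
              index_label=index_label)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               allow_nan=True) + "\n")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages, write tables and a machine-readable manifest.

    Returns the manifest dict. Any stage error is logged with the stage name
    and propagated.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    if not log.handlers:
        log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {
        "config": config.to_dict(),
        "versions": {"spnblur": _pkg_version(), "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": [],
    }

    def stage(name: str):
        log.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("syndata")
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            adata, gt = syndata.generate_dataset(sim)
            io_mod.write_dataset(adata, outdir / "dataset", ground_truth=gt)
        else:
            adata = io_mod.read_dataset(config.input["mtx"],
                                        config.input["cells"],
                                        config.input["genes"])
            gt = None
        manifest["n_cells_input"] = int(adata.n_obs)
        manifest["n_genes"] = int(adata.n_vars)
    except Exception:
        log.exception("stage syndata failed")
        raise

    try:
        stage("qc")
        thr = qc_mod.QcThresholds(species=config.species,
                                  max_mito_frac=config.max_mito_frac,
                                  min_unique_genes=config.min_unique_genes)
        adata, report = qc_mod.filter_cells(adata, thr)
        _write_json(report.to_dict(), outdir / "qc_report.json")
        manifest["n_cells_qc"] = int(adata.n_obs)
    except Exception:
        log.exception("stage qc failed")
        raise

    try:
        stage("dge")
        pb = dge_mod.aggregate_pseudobulk(adata)
        subtypes = [t for t in adata.obs["subtype"].unique()]
        subtypes = sorted(subtypes)
        hd_tables = {}
        for t in subtypes:
            res = dge_mod.dge_hd_vs_control(pb, t,
                                            weights_mode=config.weights_mode)
            hd_tables[t] = res
            _write_tsv(res, outdir / f"dge_hd_vs_control_{t}.tsv", "gene")
        contrasts = {
            "sm_d1": ("S-D1", "M-D1"), "sm_d2": ("S-D2", "M-D2"),
            "dd_s": ("S-D1", "S-D2"), "dd_m": ("M-D1", "M-D2")}
        ctl_tables = {}
        for key, (a, b) in contrasts.items():
            res = dge_mod.dge_subtype_vs_subtype(
                pb, a, b, "control", weights_mode=config.weights_mode)
            ctl_tables[key] = res
            _write_tsv(res, outdir / f"dge_control_{a}_vs_{b}.tsv", "gene")
        manifest["n_dge_rows"] = int(sum(len(v) for v in hd_tables.values()))
    except Exception:
        log.exception("stage dge failed")
        raise

    try:
        stage("markers")
        sm_markers, sm_disc = mk_mod.identify_axis_markers(
            ctl_tables["sm_d1"], ctl_tables["sm_d2"], axis="S-M",
            lfc_min=config.lfc_min, alpha=config.alpha,
            use_adjusted=config.use_adjusted_p)
        dd_markers, dd_disc = mk_mod.identify_axis_markers(
            ctl_tables["dd_s"], ctl_tables["dd_m"], axis="D1-D2",
            lfc_min=config.lfc_min, alpha=config.alpha,
            use_adjusted=config.use_adjusted_p)
        markers = pd.concat([sm_markers, dd_markers])
        _write_tsv(markers, outdir / "markers.tsv", "gene")
        _write_tsv(pd.concat([sm_disc, dd_disc]),
                   outdir / "markers_discordant.tsv", "gene")
        manifest["n_markers"] = int(len(markers))
    except Exception:
        log.exception("stage markers failed")
        raise

    try:
        stage("identity")
        mask = id_mod.detected_genes(adata, config.min_detect_frac)
        profiles = {}
        for ph in ("control", "HD"):
            profiles[ph] = {
                t: id_mod.subtype_profile(adata, t, ph, gene_mask=mask,
                                          normalization=config.normalization)
                for t in subtypes}
        losses = id_mod.distance_loss(profiles["control"], profiles["HD"],
                                      log_base=config.log_base)
        _write_tsv(losses, outdir / "loss_table.tsv")
        mean_loss = id_mod.per_celltype_mean_loss(losses)
        _write_tsv(mean_loss, outdir / "mean_loss_by_subtype.tsv")
        reg = id_mod.loss_vs_endogenous_regression(
            losses, order=config.regression_order,
            ci_level=config.regression_ci)
        _write_json(reg.to_dict(), outdir / "loss_regression.json")
        fracs = id_mod.subtype_fractions(
            adata, universe=[t for t in id_mod.SPN_SUBTYPES if t in subtypes])
        _write_tsv(fracs, outdir / "subtype_fractions.tsv")
        manifest["n_pairs"] = int(len(losses))
    except Exception:
        log.exception("stage identity failed")
        raise

    try:
        stage("dysreg")
        records = dysreg_mod.classify_directionality(
            hd_tables, lfc_min=config.lfc_min, alpha=config.alpha,
            use_adjusted=config.directionality_use_adjusted,
            mode=config.directionality_mode)
        _write_tsv(records, outdir / "directionality.tsv", "gene")
        severity = {}
        for cls in ("all", "unidirectional", "bidirectional"):
            try:
                severity[cls] = dysreg_mod.severity_by_celltype(
                    records[records["class"] != "not-dysregulated"]
                    if cls == "all" else records,
                    subtypes, directionality=cls if cls != "all" else "all"
                ).to_dict()
            except ValueError as e:
                severity[cls] = {"error": str(e)}
        _write_json(severity, outdir / "severity.json")
        if len(markers):
            direction = dysreg_mod.marker_direction_summary(records, markers,
                                                            subtypes)
        else:
            log.warning("no markers passed thresholds; direction summary "
                        "is empty")
            direction = pd.DataFrame(columns=["axis", "side", "scope",
                                              "subtype", "mean_lfc", "ci_low",
                                              "ci_high", "n"])
        _write_tsv(direction, outdir / "marker_direction.tsv")
        if config.gene_set:
            gs = dysreg_mod.gene_set_summary(hd_tables, config.gene_set)
            _write_tsv(gs, outdir / "gene_set_summary.tsv")
        manifest["n_classified"] = int((records["class"]
                                        != "not-dysregulated").sum())
    except Exception:
        log.exception("stage dysreg failed")
        raise

    _write_json(manifest, outdir / "manifest.json")
    return manifest


def _pkg_version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("spnblur")
    except PackageNotFoundError:
        return "unknown"
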