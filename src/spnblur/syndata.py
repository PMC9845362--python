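"""Synthetic snRNA-seq generator for striatal SPN subtypes.

Emulates the statistical structure the downstream analysis assumes: per-gene
negative-binomial (gamma-Poisson) counts with sample-level replicates, marker
fold-change structure along the striosome-matrix (S-M) and D1-D2 axes, an
idiosyncratic O-D2 identity, disease-phenotype identity blurring with a
per-subtype severity gradient, cell-type-nonspecific (uniform) shifts,
library-size and mitochondrial-fraction variation, and optional subtype
depletion. Every injected effect is recorded in a :class:`GroundTruth` so
parameter-recovery tests can compare estimates against the truth.

The expression model, on log2 scale, for gene g in a cell of subtype t,
sample s, phenotype ph:

    log2 mu = log2(baseline_g) + endo(g, t) + hd(g, t) * [ph == HD]
              + sample_offset(g, s)

Cell counts are NB draws with mean ``lib_size * softmax-normalized mu`` split
between mitochondrial and nuclear gene blocks according to the cell's drawn
mitochondrial fraction; variance = mu + dispersion * mu**2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

DEFAULT_SUBTYPES = ("M-D1", "S-D1", "M-D2", "S-D2", "O-D2")
CANONICAL_SUBTYPES = ("M-D1", "S-D1", "M-D2", "S-D2")
DEFAULT_SEVERITY = {"M-D1": 0.8, "S-D1": 1.0, "M-D2": 1.0, "S-D2": 1.5, "O-D2": 2.0}


class ConfigError(ValueError):
    """Raised when a :class:`SimConfig` field is invalid; names the field."""


def compartment_of(subtype: str) -> str:
    """Striatal compartment of a subtype label: 'S' (striosome) or 'M' (matrix).

    O-* subtypes are treated as striosome-like (O-D2 sits transcriptomically
    closer to the striosomal identity).
    """
    if subtype.startswith("S-") or subtype.startswith("O-"):
        return "S"
    if subtype.startswith("M-"):
        return "M"
    raise ConfigError(f"subtypes: cannot infer compartment from label {subtype!r}")


def pathway_of(subtype: str) -> str:
    """Projection pathway of a subtype label: 'D1' (direct) or 'D2' (indirect)."""
    if subtype.endswith("-D1"):
        return "D1"
    if subtype.endswith("-D2"):
        return "D2"
    raise ConfigError(f"subtypes: cannot infer pathway from label {subtype!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dataset.

    Fractions are of the gene universe; log-fold-changes are log2; the
    baseline and library-size laws are lognormal on the natural-log scale.
    ``blur_*`` is the fraction of a marker's endogenous contrast cancelled in
    the disease phenotype, split symmetrically between the two sides and
    scaled per subtype by ``severity_weights``.
    """

    n_genes: int = 2000
    subtypes: Sequence[str] = DEFAULT_SUBTYPES
    n_samples_per_phenotype: int = 4
    cells_per_sample_per_subtype: int | Mapping[str, int] = 150
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.3
    marker_fraction_sm: float = 0.10
    marker_fraction_d1d2: float = 0.10
    marker_fraction_od2: float = 0.05
    marker_lfc_mean: float = 1.0
    marker_lfc_sd: float = 0.4
    marker_lfc_floor: float = 0.25
    blur_sm: float = 0.5
    blur_d1d2: float = 0.1
    blur_od2: float | None = None  # defaults to blur_sm
    severity_weights: Mapping[str, float] | None = None
    uniform_shift_sd: float = 0.2
    uniform_shift_fraction: float = 0.3
    depletion: Mapping[str, float] | None = None
    library_size_log_mean: float = float(np.log(5000.0))
    library_size_log_sd: float = 0.3
    mito_gene_fraction: float = 0.01
    mito_fraction_beta_params: tuple[float, float] = (2.0, 98.0)
    mito_outlier_fraction: float = 0.02
    mito_outlier_beta_params: tuple[float, float] = (2.0, 8.0)
    sample_effect_sd: float = 0.05
    seed: int = 0

    def resolved_severity(self) -> dict[str, float]:
        if self.severity_weights is None:
            return {t: DEFAULT_SEVERITY.get(t, 1.0) for t in self.subtypes}
        return dict(self.severity_weights)

    def resolved_depletion(self) -> dict[str, float]:
        if self.depletion is None:
            return {t: 1.0 for t in self.subtypes}
        out = {t: 1.0 for t in self.subtypes}
        out.update(self.depletion)
        return out

    def cells_for(self, subtype: str) -> int:
        if isinstance(self.cells_per_sample_per_subtype, Mapping):
            return int(self.cells_per_sample_per_subtype[subtype])
        return int(self.cells_per_sample_per_subtype)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes: must be a positive integer")
        if len(set(self.subtypes)) != len(self.subtypes):
            raise ConfigError("subtypes: labels must be unique")
        for t in self.subtypes:
            compartment_of(t), pathway_of(t)
            if self.cells_for(t) < 1:
                raise ConfigError("cells_per_sample_per_subtype: must be >= 1")
        if self.n_samples_per_phenotype < 1:
            raise ConfigError("n_samples_per_phenotype: must be a positive integer")
        for name in ("marker_fraction_sm", "marker_fraction_d1d2",
                     "marker_fraction_od2", "mito_gene_fraction",
                     "uniform_shift_fraction", "mito_outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1]")
        total = (self.marker_fraction_sm + self.marker_fraction_d1d2
                 + self.marker_fraction_od2 + self.mito_gene_fraction)
        if total > 1.0:
            raise ConfigError("marker fractions + mito_gene_fraction exceed 1")
        for name in ("blur_sm", "blur_d1d2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1]")
        if self.blur_od2 is not None and not 0.0 <= self.blur_od2 <= 1.0:
            raise ConfigError("blur_od2: must be in [0, 1] or None")
        sev = self.resolved_severity()
        if set(sev) != set(self.subtypes):
            raise ConfigError("severity_weights: must be keyed exactly by subtypes")
        dep = self.resolved_depletion()
        if self.depletion is not None and not set(self.depletion) <= set(self.subtypes):
            raise ConfigError("depletion: unknown subtype label")
        for t, r in dep.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError("depletion: retention fractions must be in [0, 1]")
        for name in ("baseline_log_sd", "library_size_log_sd", "sample_effect_sd",
                     "uniform_shift_sd", "marker_lfc_sd", "dispersion"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if self.marker_lfc_floor < 0:
            raise ConfigError("marker_lfc_floor: must be >= 0")
        for name in ("mito_fraction_beta_params", "mito_outlier_beta_params"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigError(f"{name}: Beta parameters must be > 0")


def null_config(**overrides) -> SimConfig:
    """A configuration with no disease effects and no depletion."""
    base = SimConfig(blur_sm=0.0, blur_d1d2=0.0, uniform_shift_sd=0.0)
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Record of every injected simulation effect.

    genes : per-gene table — axis ('S-M' | 'D1-D2' | 'none'), side
        ('striosome' | 'matrix' | 'D1' | 'D2' | ''), endogenous log2
        within-axis contrast, O-D2 identity lfc, mitochondrial flag.
    hd_lfc : genes x subtypes table of injected disease log2FC.
    directionality : implied class per gene from the signs of hd_lfc over the
        four canonical subtypes ('unidirectional' | 'bidirectional' | 'none').
    depletion : per-subtype cell-retention fraction in the disease phenotype.
    """

    genes: pd.DataFrame
    hd_lfc: pd.DataFrame
    depletion: pd.Series
    directionality: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if not self.genes.index.is_unique:
            raise ValueError("GroundTruth: duplicated gene ids")
        canon = [t for t in CANONICAL_SUBTYPES if t in self.hd_lfc.columns]
        sub = self.hd_lfc[canon].to_numpy()
        pos = (sub > 0).any(axis=1)
        neg = (sub < 0).any(axis=1)
        cls = np.where(pos & neg, "bidirectional",
                       np.where(pos | neg, "unidirectional", "none"))
        self.directionality = pd.Series(cls, index=self.hd_lfc.index,
                                        name="directionality")


def _truncated_lfc(rng: np.random.Generator, n: int, mean: float, sd: float,
                   floor: float) -> np.ndarray:
    """|N(mean, sd)| magnitudes, redrawn until >= floor."""
    out = np.abs(rng.normal(mean, sd, n))
    for _ in range(1000):
        bad = out < floor
        if not bad.any():
            break
        out[bad] = np.abs(rng.normal(mean, sd, int(bad.sum())))
    out[out < floor] = floor
    return out


def inject_identity_blurring(contrast_lfc: np.ndarray, axis: str, blur: float,
                             severity_weights: Mapping[str, float],
                             subtypes: Sequence[str] = DEFAULT_SUBTYPES) -> pd.DataFrame:
    """Per-subtype disease log2FC implementing symmetric identity blurring.

    A marker whose endogenous contrast ``c`` favors one side of ``axis``
    loses ``blur * c`` of that contrast in the disease phenotype, half taken
    from its own side (down) and half added to the opposite side (up), each
    half scaled by the subtype's severity weight:

        shift(t) = -(blur / 2) * c * w_t   on the marker's favored side,
        shift(t) = +(blur / 2) * c * w_t   on the opposite side.

    ``axis`` is 'S-M' (sides = compartments, positive c favors striosome),
    'D1-D2' (sides = pathways, positive c favors D1) or 'O-D2' (positive c
    favors O-D2 against all other subtypes).
    """
    if not 0.0 <= blur <= 1.0:
        raise ValueError("blur must be in [0, 1]")
    missing = [t for t in subtypes if t not in severity_weights]
    if missing:
        raise ValueError(f"severity_weights missing subtypes: {missing}")
    c = np.asarray(contrast_lfc, dtype=float)
    out = np.zeros((c.size, len(subtypes)))
    for j, t in enumerate(subtypes):
        if axis == "S-M":
            on_side = compartment_of(t) == "S"
        elif axis == "D1-D2":
            on_side = pathway_of(t) == "D1"
        elif axis == "O-D2":
            on_side = t.startswith("O-")
        else:
            raise ValueError(f"unknown axis {axis!r}")
        sign = -1.0 if on_side else 1.0
        out[:, j] = sign * (blur / 2.0) * c * severity_weights[t]
    return pd.DataFrame(out, columns=list(subtypes))


def _endogenous_effects(cfg: SimConfig, rng: np.random.Generator):
    """Assign gene roles and endogenous per-subtype log2 offsets."""
    G = cfg.n_genes
    n_mito = int(round(G * cfg.mito_gene_fraction))
    n_sm = int(round(G * cfg.marker_fraction_sm))
    n_dd = int(round(G * cfg.marker_fraction_d1d2))
    n_od2 = int(round(G * cfg.marker_fraction_od2))
    perm = rng.permutation(G)
    idx_mito = perm[:n_mito]
    idx_sm = perm[n_mito:n_mito + n_sm]
    idx_dd = perm[n_mito + n_sm:n_mito + n_sm + n_dd]
    idx_od2 = perm[n_mito + n_sm + n_dd:n_mito + n_sm + n_dd + n_od2]

    axis = np.full(G, "none", dtype=object)
    side = np.full(G, "", dtype=object)
    endo_lfc = np.zeros(G)
    od2_lfc = np.zeros(G)

    mag = _truncated_lfc(rng, n_sm, cfg.marker_lfc_mean, cfg.marker_lfc_sd,
                         cfg.marker_lfc_floor)
    sgn = rng.choice([1.0, -1.0], n_sm)
    axis[idx_sm] = "S-M"
    side[idx_sm] = np.where(sgn > 0, "striosome", "matrix")
    endo_lfc[idx_sm] = sgn * mag

    mag = _truncated_lfc(rng, n_dd, cfg.marker_lfc_mean, cfg.marker_lfc_sd,
                         cfg.marker_lfc_floor)
    sgn = rng.choice([1.0, -1.0], n_dd)
    axis[idx_dd] = "D1-D2"
    side[idx_dd] = np.where(sgn > 0, "D1", "D2")
    endo_lfc[idx_dd] = sgn * mag

    # O-D2 identity genes: elevated (or depressed) in O-D2 against all others.
    od2_lfc[idx_od2] = rng.choice([1.0, -1.0], n_od2) * _truncated_lfc(
        rng, n_od2, cfg.marker_lfc_mean, cfg.marker_lfc_sd, cfg.marker_lfc_floor)

    is_mito = np.zeros(G, dtype=bool)
    is_mito[idx_mito] = True
    names = np.array([f"mt-g{i:05d}" if is_mito[i] else f"g{i:05d}"
                      for i in range(G)], dtype=object)

    subtypes = list(cfg.subtypes)
    endo = np.zeros((G, len(subtypes)))
    for j, t in enumerate(subtypes):
        comp_sign = 0.5 if compartment_of(t) == "S" else -0.5
        path_sign = 0.5 if pathway_of(t) == "D1" else -0.5
        od2_sign = 0.5 if t.startswith("O-") else -0.5
        endo[:, j] += np.where(axis == "S-M", comp_sign * endo_lfc, 0.0)
        endo[:, j] += np.where(axis == "D1-D2", path_sign * endo_lfc, 0.0)
        endo[:, j] += od2_sign * od2_lfc

    genes = pd.DataFrame(
        {"axis": axis, "side": side, "endogenous_lfc": endo_lfc,
         "od2_identity_lfc": od2_lfc, "is_mito": is_mito},
        index=pd.Index(names, name="gene"),
    )
    return genes, endo


def _hd_effects(cfg: SimConfig, genes: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    """Injected disease log2FC per gene per subtype (blurring + shared shift)."""
    subtypes = list(cfg.subtypes)
    sev = cfg.resolved_severity()
    G = len(genes)
    hd = np.zeros((G, len(subtypes)))

    is_sm = (genes["axis"] == "S-M").to_numpy()
    is_dd = (genes["axis"] == "D1-D2").to_numpy()
    endo = genes["endogenous_lfc"].to_numpy()
    od2 = genes["od2_identity_lfc"].to_numpy()

    hd[is_sm] += inject_identity_blurring(endo[is_sm], "S-M", cfg.blur_sm,
                                          sev, subtypes).to_numpy()
    hd[is_dd] += inject_identity_blurring(endo[is_dd], "D1-D2", cfg.blur_d1d2,
                                          sev, subtypes).to_numpy()
    blur_od2 = cfg.blur_sm if cfg.blur_od2 is None else cfg.blur_od2
    has_od2 = od2 != 0
    hd[has_od2] += inject_identity_blurring(od2[has_od2], "O-D2", blur_od2,
                                            sev, subtypes).to_numpy()

    # Cell-type-nonspecific component: one shared shift per affected gene.
    if cfg.uniform_shift_sd > 0 and cfg.uniform_shift_fraction > 0:
        hit = rng.random(G) < cfg.uniform_shift_fraction
        shift = np.where(hit, rng.normal(0.0, cfg.uniform_shift_sd, G), 0.0)
        hd += shift[:, None]
    else:
        rng.random(G)  # keep the stream aligned across configurations
        rng.normal(0.0, 1.0, G)

    return pd.DataFrame(hd, index=genes.index, columns=subtypes)


def retained_cells(n_cells: int, retention: float) -> int:
    """Cells kept after depletion: round(n * retention), at least 0."""
    return int(round(n_cells * retention))


def generate_dataset(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a labelled count matrix and the ground truth behind it.

    Returns an :class:`anndata.AnnData` (cells x genes, CSR counts) with
    ``obs`` columns cell_id index, sample, phenotype ('control' | 'HD'),
    subtype and realized mito_frac, and ``var`` carrying the gene-role table.
    Identical configs (including seed) produce bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, endo = _endogenous_effects(config, rng)
    hd_lfc = _hd_effects(config, genes, rng)
    subtypes = list(config.subtypes)
    sev_dep = config.resolved_depletion()

    baseline_log2 = np.log2(rng.lognormal(config.baseline_log_mean,
                                          config.baseline_log_sd, config.n_genes))
    samples = ([f"ctrl{i + 1}" for i in range(config.n_samples_per_phenotype)]
               + [f"hd{i + 1}" for i in range(config.n_samples_per_phenotype)])
    phen_of = {s: ("control" if s.startswith("ctrl") else "HD") for s in samples}
    sample_off = {s: rng.normal(0.0, config.sample_effect_sd, config.n_genes)
                  for s in samples}

    is_mito = genes["is_mito"].to_numpy()
    use_mito = is_mito.any()
    disp = float(config.dispersion)

    blocks, obs_rows = [], []
    for s in samples:
        is_hd = phen_of[s] == "HD"
        for j, t in enumerate(subtypes):
            n = config.cells_for(t)
            if is_hd:
                n = retained_cells(n, sev_dep[t])
            if n == 0:
                continue
            log2_theta = (baseline_log2 + endo[:, j] + sample_off[s]
                          + (hd_lfc[t].to_numpy() if is_hd else 0.0))
            theta = np.exp2(log2_theta)
            lib = rng.lognormal(config.library_size_log_mean,
                                config.library_size_log_sd, n)
            if use_mito:
                mfrac = rng.beta(*config.mito_fraction_beta_params, n)
                if config.mito_outlier_fraction > 0:
                    out = rng.random(n) < config.mito_outlier_fraction
                    mfrac[out] = rng.beta(*config.mito_outlier_beta_params,
                                          int(out.sum()))
                p_nuc = theta.copy()
                p_nuc[is_mito] = 0.0
                p_nuc /= p_nuc.sum()
                p_mit = np.where(is_mito, theta, 0.0)
                p_mit /= p_mit.sum()
                mu = (p_nuc[:, None] * (lib * (1.0 - mfrac))[None, :]
                      + p_mit[:, None] * (lib * mfrac)[None, :])
            else:
                mu = (theta / theta.sum())[:, None] * lib[None, :]
            if disp > 0:
                size = 1.0 / disp
                counts = rng.negative_binomial(size, size / (size + mu))
            else:
                counts = rng.poisson(mu)
            blocks.append(counts.astype(np.int64))
            for i in range(n):
                obs_rows.append((f"{s}.{t}.{i:04d}", s, phen_of[s], t))

    X = np.concatenate([b.T for b in blocks], axis=0)  # cells x genes
    obs = pd.DataFrame(obs_rows, columns=["cell_id", "sample", "phenotype",
                                          "subtype"]).set_index("cell_id")
    total = X.sum(axis=1)
    obs["mito_frac"] = (X[:, is_mito].sum(axis=1) / np.maximum(total, 1)
                        if use_mito else 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anndata chattiness about str indices
        adata = ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=genes.copy())
    gt = GroundTruth(genes=genes, hd_lfc=hd_lfc,
                     depletion=pd.Series(sev_dep, name="retention"))
    return adata, gt
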