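"""End-to-end SPAD estimation pipeline.

Stage order follows the analysis the package implements:

1. load spectra (CSV) or generate a seeded synthetic dataset;
2. SNV scatter correction and SPA wavelength selection (reported as the
   selected-band correlation table);
3. GL fractional differentiation at orders 0.0-1.0 (step 0.1);
4. per-order single-band correlation screening;
5. exhaustive two-band index correlation maps (FDI/FRI/FNDI) and best-pair
   extraction;
6. a model-comparison grid: top-{3,4,5} single bands, top-{7,8,9} index
   features, and their fusion, each fit with a fixed-hyperparameter LSSVM
   and an SMA-tuned LSSVM on one shared seeded 75/25 split;
7. a report of every table plus provenance (seeds, config hash).

Per-stage seeds are derived from the master seed by hashing the stage
name, so adding a stage never perturbs the random streams of earlier ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .dataset import ConfigError, SpectraSet, read_spectra_csv
from .fracdiff import DEFAULT_ALPHAS, DiffSpectraSet, diff_spectra
from .indices import IndexFeature, best_pairs, compute_index, correlation_map
from .lssvm import (
    DEFAULT_SEARCH_BOUNDS,
    FitReport,
    evaluate,
    lssvm_predict,
    lssvm_train,
    sma_lssvm_fit,
)
from .preprocessing import snv_matrix, spa_select
from .screening import (
    ScreeningReport,
    SingleBandFeature,
    rank_features,
    screen_orders,
    significance_star,
)
from .sma import SMAConfig
from .synthetic import SynthConfig, generate_dataset

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed from the master seed via a stage-name hash (< 2^31)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on."""

    csv_path: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    master_seed: int = 0
    # SPA stage
    spa_size_min: int = 5
    spa_size_max: int = 40
    spa_folds: int = 5
    spa_step_nm: float = 2.0
    spa_on_snv: bool = True
    # fractional differentiation
    alphas: tuple = DEFAULT_ALPHAS
    window: int | None = None
    edge_trim: int | None = None
    # index maps
    index_kinds: tuple = ("FDI", "FRI", "FNDI")
    resample_step_nm: float = 2.0
    pairs_per_map: int = 20
    # experiment grid
    single_counts: tuple = (3, 4, 5)
    index_counts: tuple = (7, 8, 9)
    # models
    train_frac: float = 0.75
    default_gamma: float = 100.0
    default_sigma2: float = 1.0
    sma_pop: int = 20
    sma_iter: int = 40
    sma_z: float = 0.03
    search_bounds: tuple = DEFAULT_SEARCH_BOUNDS

    def validate(self) -> None:
        if self.csv_path is not None and not Path(self.csv_path).exists():
            raise ConfigError(f"csv_path does not exist: {self.csv_path}")
        if not (0 < self.train_frac < 1):
            raise ConfigError(f"train_frac must be in (0, 1), got {self.train_frac}")
        for name in ("single_counts", "index_counts", "index_kinds", "alphas"):
            if not getattr(self, name):
                raise ConfigError(f"{name} must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        for tup in ("alphas", "index_kinds", "single_counts", "index_counts",
                    "search_bounds"):
            if tup in raw:
                raw[tup] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[tup]
                )
        return cls(synth=synth, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All tables one run produces, plus the provenance to recompute them."""

    table_spa: pd.DataFrame
    table_single: pd.DataFrame
    table_index_best: pd.DataFrame
    table_models: pd.DataFrame
    best_cell: dict
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "best_cell": self.best_cell,
            "table_spa": self.table_spa.to_dict(orient="records"),
            "table_single": self.table_single.to_dict(orient="records"),
            "table_index_best": self.table_index_best.to_dict(orient="records"),
            "table_models": self.table_models.to_dict(orient="records"),
        }
        return json.dumps(payload, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# stage helpers


def _grid_indices(wavelengths: np.ndarray, step_nm: float) -> np.ndarray:
    targets = np.arange(wavelengths[0], wavelengths[-1] + step_nm * 0.5, step_nm)
    idx = np.searchsorted(wavelengths, targets)
    idx = np.clip(idx, 1, wavelengths.size - 1)
    left = np.abs(wavelengths[idx - 1] - targets) <= np.abs(wavelengths[idx] - targets)
    return np.unique(np.where(left, idx - 1, idx))


def _spa_table(data: SpectraSet, cfg: PipelineConfig) -> pd.DataFrame:
    keep = _grid_indices(data.wavelengths_nm, cfg.spa_step_nm)
    X = data.reflectance[:, keep]
    Xp = snv_matrix(X) if cfg.spa_on_snv else X
    size_max = min(cfg.spa_size_max, keep.size - 1, data.n_samples - 2)
    res = spa_select(
        Xp,
        data.spad,
        size_min=min(cfg.spa_size_min, size_max),
        size_max=size_max,
        eval_folds=cfg.spa_folds,
        seed=stage_seed(cfg.master_seed, "spa"),
        wavelengths_nm=data.wavelengths_nm[keep],
    )
    rows = []
    n = data.n_samples
    for bi, wl in zip(res.selected_band_indices, res.selected_wavelengths_nm):
        x = data.reflectance[:, keep[bi]]
        r, p = stats.pearsonr(x, data.spad)
        rows.append(
            {"wavelength_nm": wl, "r": float(r), "p": float(p),
             "star": significance_star(p)}
        )
    return pd.DataFrame(rows)


def _index_ranking(
    diffs: list[DiffSpectraSet], spad: np.ndarray, cfg: PipelineConfig
) -> tuple[list[tuple[IndexFeature, float]], pd.DataFrame]:
    """All best pairs merged across (kind, order), plus the per-map-best table."""
    merged: list[tuple[IndexFeature, float]] = []
    table_rows = []
    for kind in cfg.index_kinds:
        for d in diffs:
            cmap = correlation_map(d, spad, kind, cfg.resample_step_nm)
            pairs = best_pairs(cmap, cfg.pairs_per_map)
            merged.extend(pairs)
            f0, r0 = pairs[0]
            table_rows.append(
                {"kind": kind, "alpha": d.alpha, "band_i_nm": f0.band_i_nm,
                 "band_j_nm": f0.band_j_nm, "r": r0}
            )
    seen = set()
    dedup = []
    for f, r in sorted(
        merged, key=lambda t: (-abs(t[1]), t[0].band_i_nm, t[0].band_j_nm,
                               t[0].alpha, t[0].kind)
    ):
        key = (f.kind, f.alpha, f.band_i_nm, f.band_j_nm)
        if key not in seen:
            seen.add(key)
            dedup.append((f, r))
    return dedup, pd.DataFrame(table_rows)


def _feature_matrix(
    feats, diffs_by_alpha: dict[float, DiffSpectraSet]
) -> np.ndarray:
    cols = []
    for f in feats:
        d = diffs_by_alpha[round(float(f.alpha), 6)]
        if isinstance(f, SingleBandFeature):
            i = int(np.argmin(np.abs(d.wavelengths_nm - f.band_nm)))
            cols.append(d.diff_reflectance[:, i])
        else:
            cols.append(compute_index(d, f))
    return np.column_stack(cols)


def _feature_label(f) -> str:
    if isinstance(f, SingleBandFeature):
        return f"R^{f.alpha:g}({f.band_nm:.2f})"
    return f"{f.kind}^{f.alpha:g}({f.band_i_nm:.2f},{f.band_j_nm:.2f})"


def _fit_cell(
    X: np.ndarray,
    y: np.ndarray,
    tr: np.ndarray,
    te: np.ndarray,
    cfg: PipelineConfig,
    cell_name: str,
) -> list[dict]:
    """Fixed-hyperparameter LSSVM and SMA-LSSVM rows for one feature set."""
    ok = np.all(np.isfinite(X), axis=1)  # masked index samples drop out here
    tr = tr[ok[tr]]
    te = te[ok[te]]
    rows = []
    m0 = lssvm_train(X[tr], y[tr], cfg.default_gamma, cfg.default_sigma2)
    t0 = evaluate(y[tr], lssvm_predict(m0, X[tr]))
    v0 = evaluate(y[te], lssvm_predict(m0, X[te]))
    rows.append(
        {"cell": cell_name, "model": "LSSVM",
         "gamma": cfg.default_gamma, "sigma2": cfg.default_sigma2,
         "r2_standard_fit": t0["r2_standard"], "r2_uncentered_fit": t0["r2_uncentered"],
         "rmse_fit": t0["rmse"],
         "r2_standard_heldout": v0["r2_standard"],
         "r2_uncentered_heldout": v0["r2_uncentered"], "rmse_heldout": v0["rmse"],
         "n_fit": int(tr.size), "n_heldout": int(te.size)}
    )
    (g_lo, g_hi), (s_lo, s_hi) = cfg.search_bounds
    sma_cfg = SMAConfig(
        lb=[g_lo, s_lo], ub=[g_hi, s_hi], pop_size=cfg.sma_pop,
        max_iter=cfg.sma_iter, z=cfg.sma_z,
        seed=stage_seed(cfg.master_seed, f"sma:{cell_name}"),
    )
    _, rep = sma_lssvm_fit(
        X[tr], y[tr], X[te], y[te], sma_cfg=sma_cfg, search_bounds=cfg.search_bounds
    )
    rows.append(
        {"cell": cell_name, "model": "SMA-LSSVM",
         "gamma": rep.gamma, "sigma2": rep.sigma2,
         "r2_standard_fit": rep.r2_standard_train,
         "r2_uncentered_fit": rep.r2_uncentered_train, "rmse_fit": rep.rmse_train,
         "r2_standard_heldout": rep.r2_standard_val,
         "r2_uncentered_heldout": rep.r2_uncentered_val,
         "rmse_heldout": rep.rmse_val,
         "n_fit": int(tr.size), "n_heldout": int(te.size)}
    )
    return rows


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(cfg: PipelineConfig, data: SpectraSet | None = None) -> RunReport:
    """Execute every stage and return the full report.

    ``data`` may be passed directly (e.g. a pre-built dataset); otherwise
    it is read from ``cfg.csv_path`` or generated from ``cfg.synth``.
    """
    cfg.validate()
    stage = "load"
    try:
        if data is None:
            data = (
                read_spectra_csv(cfg.csv_path)
                if cfg.csv_path is not None
                else generate_dataset(cfg.synth)
            )

        stage = "spa"
        table_spa = _spa_table(data, cfg)

        stage = "fracdiff"
        diffs = diff_spectra(data, cfg.alphas, window=cfg.window,
                             edge_trim=cfg.edge_trim)
        diffs_by_alpha = {round(d.alpha, 6): d for d in diffs}

        stage = "screening"
        report: ScreeningReport = screen_orders(diffs, data.spad)
        table_single = report.per_order.copy()

        stage = "indexmap"
        index_ranked, table_index_best = _index_ranking(diffs, data.spad, cfg)

        stage = "models"
        n = data.n_samples
        rng = np.random.default_rng(stage_seed(cfg.master_seed, "split"))
        perm = rng.permutation(n)
        n_tr = int(np.floor(cfg.train_frac * n))
        tr, te = perm[:n_tr], perm[n_tr:]

        rows: list[dict] = []
        cell_feats: dict[str, list] = {}
        singles_ranked = rank_features(report, None, len(report.features))
        for k in cfg.single_counts:
            feats = [f for f, _ in singles_ranked[:k]]
            name = f"single-{k}"
            cell_feats[name] = feats
            X = _feature_matrix(feats, diffs_by_alpha)
            rows.extend(_fit_cell(X, data.spad, tr, te, cfg, name))
        for k in cfg.index_counts:
            feats = [f for f, _ in index_ranked[:k]]
            name = f"index-{k}"
            cell_feats[name] = feats
            X = _feature_matrix(feats, diffs_by_alpha)
            rows.extend(_fit_cell(X, data.spad, tr, te, cfg, name))

        # fusion: the best single-band cell's features plus the best index
        # cell's features, judged by SMA-LSSVM held-out RMSE
        def _best(prefix: str) -> str:
            cand = [
                r for r in rows
                if r["cell"].startswith(prefix) and r["model"] == "SMA-LSSVM"
            ]
            return min(cand, key=lambda r: r["rmse_heldout"])["cell"]

        fusion = cell_feats[_best("single-")] + cell_feats[_best("index-")]
        cell_feats["fusion"] = fusion
        X = _feature_matrix(fusion, diffs_by_alpha)
        rows.extend(_fit_cell(X, data.spad, tr, te, cfg, "fusion"))

        table_models = pd.DataFrame(rows)
        ib = int(table_models["rmse_heldout"].idxmin())
        best_row = table_models.loc[ib]
        best_cell = {
            "cell": best_row["cell"],
            "model": best_row["model"],
            "rmse_heldout": float(best_row["rmse_heldout"]),
            "r2_standard_heldout": float(best_row["r2_standard_heldout"]),
            "features": [_feature_label(f) for f in cell_feats[best_row["cell"]]],
        }
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage '{stage}' failed (config {cfg.config_hash()}): {exc}"
        ) from exc

    provenance = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "stage_seeds": {
            s: stage_seed(cfg.master_seed, s) for s in ("spa", "split")
        },
        "n_samples": int(data.n_samples),
        "n_bands": int(data.n_bands),
        "version": __version__,
    }
    return RunReport(
        table_spa=table_spa,
        table_single=table_single,
        table_index_best=table_index_best,
        table_models=table_models,
        best_cell=best_cell,
        provenance=provenance,
    )


def write_report(report: RunReport, outdir) -> None:
    """Serialize every table as CSV plus a combined JSON report.

    Output is byte-deterministic for a fixed config and master seed: float
    formatting uses Python repr throughout.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={report.provenance['config_hash']}\n"
    for name in ("table_spa", "table_single", "table_index_best", "table_models"):
        path = out / f"{name}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            getattr(report, name).to_csv(fh, index=False, lineterminator="\n")
    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
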