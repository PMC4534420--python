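"""End-to-end orchestration: simulate → prep → masks → significance → models.

A :class:`RunConfig` describes one run — either a synthetic subject (the
default; generator settings plus a protocol preset) or pre-existing NIfTI
inputs — together with the analysis settings. :func:`run_experiment`
executes all stages, writes tables (CSV), maps (NIfTI) and fit results
(JSON) under an output directory, and finishes with a provenance record
listing every output file with its SHA-256 hash, the full configuration and
the library versions. The same config and seed produce byte-identical CSV
and JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ASLSeries, SIRVolume, save_mask
from .exceptions import InvalidParameterError
from .masking import MaskConfig, build_masks
from .models import (fit_response_curve, fit_sqrt_law, group_histograms,
                     t_histograms)
from .phantom import PhantomConfig, sample_tissue_map
from .prep import nsa_to_minutes, split_and_subtract
from .protocol import KineticParams, Protocol, get_protocol
from .significance import (find_nonresponders, significant_fraction, t_curves,
                           time_to_significance)
from .simulate import NoiseConfig, simulate_series

log = logging.getLogger("aslpower")

__all__ = ["RunConfig", "run_experiment"]


@dataclass
class RunConfig:
    """Settings for one end-to-end run.

    Exactly one input source: generator settings (default) or paths to an
    existing series and SIR volume (``series_path`` + ``sir_path``).
    """

    out_dir: str = "aslpower_out"
    seed: int = 0
    protocol: str = "exp3"
    n_subjects: int = 1

    # input source A: synthetic
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    kinetics: KineticParams = field(default_factory=KineticParams)
    # input source B: files
    series_path: str | None = None
    sir_path: str | None = None

    # analysis settings
    alphas: tuple[float, ...] = (0.05, 0.01)
    corrections: tuple[str, ...] = ("none", "bonferroni")
    tts_alpha: float = 0.05
    tts_correction: str = "none"
    grid_step: int = 5
    bins: int = 60
    masks: MaskConfig = field(default_factory=MaskConfig)
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.series_path is None) != (self.sir_path is None):
            raise InvalidParameterError(
                "series_path and sir_path must be given together")
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if self.series_path is not None and self.n_subjects != 1:
            raise InvalidParameterError(
                "file input supports a single subject")
        if self.grid_step < 1:
            raise InvalidParameterError("grid_step must be >= 1")

    @property
    def protocol_obj(self) -> Protocol:
        return get_protocol(self.protocol)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("phantom", PhantomConfig), ("noise", NoiseConfig),
                         ("kinetics", KineticParams), ("masks", MaskConfig)):
            if key in raw and isinstance(raw[key], dict):
                if "shape" in raw[key]:
                    raw[key]["shape"] = tuple(raw[key]["shape"])
                if "voxel_size" in raw[key]:
                    raw[key]["voxel_size"] = tuple(raw[key]["voxel_size"])
                raw[key] = sub(**raw[key])
        for key in ("alphas", "corrections"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["noise"] = self.noise.as_dict()
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _thinned_grid(n_pairs: int, step: int) -> np.ndarray:
    grid = np.arange(step, n_pairs + 1, step)
    if grid.size == 0 or grid[0] > 2:
        grid = np.concatenate([[2], grid[grid > 2]])
    return grid


def _load_or_simulate(config: RunConfig, subject: int
                      ) -> tuple[ASLSeries, SIRVolume, object | None]:
    if config.series_path is not None:
        series = ASLSeries.load(config.series_path, config.protocol_obj)
        sir = SIRVolume.load(config.sir_path)
        return series, sir, None
    seed = config.seed + subject
    tmap = sample_tissue_map(config=config.phantom, seed=seed)
    series, sir = simulate_series(tmap, config.protocol_obj, config.kinetics,
                                  config.noise, seed=seed)
    return series, sir, tmap


def run_experiment(config: RunConfig) -> dict:
    """Run all stages and write the report bundle under ``config.out_dir``.

    Returns a dict with the in-memory results: significance curve table,
    fit results, mask counts and the provenance record.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    protocol = config.protocol_obj
    t0 = time.time()

    thin_grid = _thinned_grid(protocol.n_pairs, config.grid_step)
    full_grid = np.arange(2, protocol.n_pairs + 1)

    frac_rows = []
    hist_sets = []
    mean_t_rows = []
    mask_counts: dict[str, int] = {}

    for subject in range(config.n_subjects):
        series, sir, tmap = _load_or_simulate(config, subject)
        log.info("subject %d: series %s", subject, series.data.shape)
        diff = split_and_subtract(series)
        masks = build_masks(sir, config.masks)
        if subject == 0:
            mask_counts = masks.counts()
            for name, m in masks.items():
                p = out / f"mask_{name}.nii.gz"
                save_mask(m, sir.voxel_size, p)
                written.append(p)
            if tmap is not None:
                tmap.save(out / "truth")
                written += sorted(out.glob("truth_*"))

        curves_thin = t_curves(diff, thin_grid)
        wm = masks.full_wm
        for name, m in masks.items():
            if not m.any():
                log.warning("subject %d: empty mask %s", subject, name)
                continue
            for alpha in config.alphas:
                for corr in config.corrections:
                    sc = significant_fraction(curves_thin, m, alpha, corr)
                    minutes = nsa_to_minutes(sc.nsa_grid, protocol)
                    for k in range(len(sc.nsa_grid)):
                        frac_rows.append({
                            "subject": subject, "mask": name,
                            "nsa": int(sc.nsa_grid[k]),
                            "minutes": minutes[k],
                            "alpha": alpha, "correction": corr,
                            "fraction": sc.fraction[k],
                            "mask_size": sc.mask_size})

        hist_sets.append(t_histograms(curves_thin, wm, bins=config.bins))
        finite_t = np.where(np.isfinite(curves_thin.t[wm]),
                            curves_thin.t[wm], np.nan)
        mt = np.nanmean(finite_t, axis=0)
        for k in range(len(thin_grid)):
            mean_t_rows.append({"subject": subject,
                                "nsa": int(thin_grid[k]),
                                "mean_t": mt[k]})

        if subject == 0:
            curves_full = t_curves(diff, full_grid)
            tts = time_to_significance(curves_full, config.tts_alpha,
                                       config.tts_correction, wm)
            nonresp = find_nonresponders(curves_full, wm)
            p = out / "time_to_significance.nii.gz"
            import nibabel as nib  # int map (NEVER = -1), not a 0/1 mask
            nib.save(nib.Nifti1Image(tts.astype(np.int32),
                                     np.diag([*sir.voxel_size, 1.0])), str(p))
            written.append(p)
            p = out / "nonresponder_mask.nii.gz"
            save_mask(nonresp, sir.voxel_size, p)
            written.append(p)

    frac_df = pd.DataFrame(frac_rows)
    frac_path = out / "significant_fraction.csv"
    frac_df.to_csv(frac_path, index=False)
    written.append(frac_path)

    group = group_histograms(hist_sets)
    hist_rows = []
    centers = group.bin_centers
    gmean = group.group_mean
    for k, nsa in enumerate(group.nsa_grid):
        for b in range(len(centers)):
            hist_rows.append({"nsa": int(nsa), "t_bin_center": centers[b],
                              "density": gmean[k, b]})
    hist_path = out / "t_histograms.csv"
    pd.DataFrame(hist_rows).to_csv(hist_path, index=False)
    written.append(hist_path)

    # group-mean response curve (entire WM, primary alpha, uncorrected)
    wm_frac = (frac_df[(frac_df["mask"] == "full")
                       & (frac_df["alpha"] == config.alphas[0])
                       & (frac_df["correction"] == "none")]
               .groupby("nsa")["fraction"].mean())
    best, candidates = fit_response_curve(wm_frac.index.to_numpy(),
                                          100.0 * wm_frac.to_numpy())
    mean_t_df = pd.DataFrame(mean_t_rows).groupby("nsa")["mean_t"].mean()
    sqrt_fit = fit_sqrt_law(mean_t_df.index.to_numpy(),
                            mean_t_df.to_numpy())

    fits = {
        "selected_model": best.model,
        "candidates": {name: {"params": r.params,
                              "residual_error": r.residual_error,
                              "ci": {k: list(v) for k, v in r.ci.items()},
                              "converged": r.converged}
                       for name, r in candidates.items()},
        "sqrt_law": {"K": sqrt_fit.k,
                     "residual_error": sqrt_fit.residual_error,
                     "ci": list(sqrt_fit.ci)},
    }
    fit_path = out / "fits.json"
    with open(fit_path, "w") as fh:
        json.dump(fits, fh, indent=2, sort_keys=True)
    written.append(fit_path)

    if config.make_plots:
        written += _make_plots(out, frac_df, group, best, config)

    provenance = {
        "package": {"name": "aslpower", "version": __version__},
        "config": _jsonable(config.as_dict()),
        "seed": config.seed,
        "mask_counts": mask_counts,
        "versions": _versions(),
        "elapsed_seconds": round(time.time() - t0, 3),
        "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    prov_path = out / "provenance.json"
    with open(prov_path, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)

    return {"fractions": frac_df, "histograms": group, "fits": fits,
            "mask_counts": mask_counts, "provenance": provenance,
            "best_fit": best, "sqrt_fit": sqrt_fit}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _versions() -> dict[str, str]:
    import nibabel
    import scipy
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "nibabel": nibabel.__version__}


def _make_plots(out: Path, frac_df: pd.DataFrame, group, best,
                config: RunConfig) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, ax = plt.subplots(figsize=(6, 4))
    sub = frac_df[(frac_df["alpha"] == config.alphas[0])
                  & (frac_df["correction"] == "none")]
    for name, grp in sub.groupby("mask"):
        mean = grp.groupby("minutes")["fraction"].mean()
        ax.plot(mean.index, 100 * mean.values, label=name)
    ax.set_xlabel("scan time (min)")
    ax.set_ylabel("% significant voxels")
    ax.legend()
    p = out / "fraction_curves.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    gmean = group.group_mean
    for k in range(0, len(group.nsa_grid), max(1, len(group.nsa_grid) // 6)):
        ax.plot(group.bin_centers, gmean[k], label=f"NSA {group.nsa_grid[k]}")
    ax.set_xlabel("t-value")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    p = out / "t_histograms.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
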