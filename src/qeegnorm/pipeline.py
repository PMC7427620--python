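"""End-to-end orchestration: epochs in, z-maps and tidy tables out.

Stage order follows the analysis chain: re-reference -> frequency grid ->
cross-spectra -> narrow/broad band parameters -> coherence -> source
imaging -> log transform -> GSF correction -> z-scoring -> corrected
thresholds -> export.  Stages without the inputs they need (e.g. no norms
for z-scoring) are skipped with a logged notice; identical config and
inputs produce identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .broadband import BandSet, BroadBandParams, broadband_params
from .containers import EpochSet, Montage
from .headmodel import LeadField, spherical_leadfield
from .inverse import RidgeInverse, SourceSpectra
from .io_text import load_montage, read_epochs_text, read_leadfield, read_norms
from .mcstats import (MaxStatThreshold, apply_threshold,
                      max_stat_threshold_empirical, max_stat_threshold_iid)
from .norms import NormativeModel, ZMaps, transform_spectra, z_score
from .preprocess import GSF, apply_gsf, estimate_gsf, rereference
from .spectra import (CoherencePhase, CrossSpectrum, NarrowBandSpectra,
                      build_frequency_grid, coherence_phase, cross_spectrum,
                      narrowband_power)

log = logging.getLogger("qeegnorm")


@dataclass
class RunConfig:
    """Everything a run needs; written verbatim into provenance."""

    input: Optional[str] = None            # epoch text file (or pass EpochSet)
    montage: str = "10-20-19"
    reference: str = "AVG"
    fmax_hz: float = 19.5
    taper: str = "none"
    bands: Optional[dict] = None           # name -> [low, high]; None = default
    leadfield: Optional[str] = "spherical"  # path, "spherical", or None (skip)
    grid_size: int = 7
    orientation: str = "free"
    lam: object = "gcv"                    # float or "gcv"
    norms: Optional[str] = None            # scalp norms file
    source_norms: Optional[str] = None
    gsf: bool = True
    alpha: float = 0.05
    correction: str = "maxstat-iid"        # maxstat-iid | maxstat-empirical | none
    out_dir: Optional[str] = None
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """All measurements of one run, with provenance."""

    config: RunConfig
    narrowband: NarrowBandSpectra
    narrowband_log: np.ndarray
    broadband: BroadBandParams
    coherence: CoherencePhase
    cross_spectrum: CrossSpectrum
    source: Optional[SourceSpectra] = None
    source_log: Optional[np.ndarray] = None
    gsf: Optional[GSF] = None
    z_scalp: Optional[ZMaps] = None
    z_source: Optional[ZMaps] = None
    threshold: Optional[MaxStatThreshold] = None
    provenance: dict = field(default_factory=dict)


def _resolve_threshold(cfg: RunConfig, m: int,
                       norm_model: Optional[NormativeModel]
                       ) -> Optional[MaxStatThreshold]:
    if cfg.correction == "none":
        return None
    if cfg.correction == "maxstat-empirical":
        if norm_model is None or norm_model.residual_z_ is None:
            log.info("no residual fields retained; falling back to analytic "
                     "i.i.d. maximum-statistic threshold")
            return max_stat_threshold_iid(m, cfg.alpha)
        return max_stat_threshold_empirical(norm_model.residual_z_, cfg.alpha)
    if cfg.correction == "maxstat-iid":
        return max_stat_threshold_iid(m, cfg.alpha)
    raise ValueError(f"unknown correction {cfg.correction!r}")


def run_pipeline(cfg: RunConfig, epochs: EpochSet | None = None) -> ResultBundle:
    """Execute the full analysis chain for one subject."""
    if epochs is None:
        if cfg.input is None:
            raise ValueError("either cfg.input or an EpochSet is required")
        epochs = read_epochs_text(cfg.input)

    # (a) reference
    if epochs.reference != cfg.reference:
        epochs = rereference(epochs, cfg.reference)

    # (c,d) frequency grid + cross-spectra + narrow band
    grid = build_frequency_grid(epochs.n_samples, epochs.fs, cfg.fmax_hz)
    cs = cross_spectrum(epochs, grid, taper=cfg.taper)
    nb = narrowband_power(cs)
    y_scalp = transform_spectra(nb.power)

    # broad band
    bands = BandSet(cfg.bands) if cfg.bands else BandSet()
    bb = broadband_params(nb, bands)

    # (e) coherence and phase
    coh = coherence_phase(cs)

    # (f) source imaging
    source = source_log = None
    imager = None
    if cfg.leadfield is not None:
        if cfg.leadfield == "spherical":
            montage = load_montage(cfg.montage).subset(epochs.channel_labels)
            lf = spherical_leadfield(montage, grid_size=cfg.grid_size,
                                     orientation_mode=cfg.orientation)
        else:
            lf = read_leadfield(cfg.leadfield)
        imager = RidgeInverse(lam=cfg.lam).fit(lf, cs)
        source = imager.transform(cs)
        source_log = transform_spectra(source.power)
    else:
        log.info("no lead field configured; source stage skipped")

    # (b,g) GSF + z-scoring
    gsf_est = None
    z_scalp = z_source = None
    scalp_model = read_norms(cfg.norms) if cfg.norms else None
    source_model = read_norms(cfg.source_norms) if cfg.source_norms else None
    if scalp_model is not None:
        order = scalp_model.match_locations(nb.channel_labels)
        y = y_scalp[order]
        mu, _ = scalp_model.predict(epochs.subject.age)
        if cfg.gsf:
            gsf_est = estimate_gsf(y, mu)
            y = apply_gsf(y, gsf_est)
        z_scalp = z_score(y, scalp_model, epochs.subject.age,
                          state=epochs.subject.state)
    else:
        log.info("no scalp norms configured; scalp z stage skipped")
    if source_model is not None and source_log is not None:
        ys = source_log
        if gsf_est is not None:
            # a single sensor gain propagates linearly to source power
            ys = apply_gsf(ys, gsf_est)
        z_source = z_score(ys, source_model, epochs.subject.age,
                           state=epochs.subject.state)

    # (g) corrected thresholds
    threshold = None
    zref = z_source if z_source is not None else z_scalp
    if zref is not None:
        threshold = _resolve_threshold(cfg, zref.z.size, scalp_model)
        if threshold is not None:
            for zm in (z_scalp, z_source):
                if zm is not None:
                    apply_threshold(zm, MaxStatThreshold(
                        alpha=threshold.alpha, m=zm.z.size,
                        value=(threshold.value if cfg.correction != "maxstat-iid"
                               else max_stat_threshold_iid(zm.z.size,
                                                           cfg.alpha).value),
                        method=threshold.method))

    provenance = {
        "software": f"qeegnorm {__version__}",
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "norms": (f"{scalp_model.state}/{scalp_model.level}/"
                  f"n={scalp_model.n_subjects_}" if scalp_model else None),
        "lambda": (float(imager.lambda_) if imager is not None
                   and np.isscalar(imager.lambda_) else None),
        "coherence_convention": "magnitude-squared",
    }
    bundle = ResultBundle(config=cfg, narrowband=nb, narrowband_log=y_scalp,
                          broadband=bb, coherence=coh, cross_spectrum=cs,
                          source=source, source_log=source_log, gsf=gsf_est,
                          z_scalp=z_scalp, z_source=z_source,
                          threshold=threshold, provenance=provenance)
    if cfg.out_dir:
        export_maps(bundle, cfg.out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_maps(b: ResultBundle, outdir) -> dict:
    """Write tidy CSV tables (and provenance JSON) for every measure."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    nb = b.narrowband
    rows = {
        "channel": np.repeat(nb.channel_labels, nb.grid.n_bins),
        "frequency_hz": np.tile(nb.grid.display_labels_hz,
                                len(nb.channel_labels)),
        "power_uv2": nb.power.ravel(),
        "log10_power": b.narrowband_log.ravel(),
    }
    if b.z_scalp is not None:
        zfull = np.full(nb.power.shape, np.nan)
        order = {c.lower(): i for i, c in enumerate(nb.channel_labels)}
        for j, loc in enumerate(b.z_scalp.locations):
            zfull[order[loc.lower()]] = b.z_scalp.z[j]
        rows["z"] = zfull.ravel()
    pd.DataFrame(rows).to_csv(outdir / "narrowband.csv", index=False,
                              float_format="%.10g")
    written["narrowband"] = outdir / "narrowband.csv"

    bb = b.broadband
    recs = []
    for bi, band in enumerate(bb.bands):
        for ci, ch in enumerate(bb.channel_labels):
            recs.append({"measure": "AP", "band": band, "channel": ch,
                         "value": bb.ap[bi, ci]})
            recs.append({"measure": "MF", "band": band, "channel": ch,
                         "value": bb.mf[bi, ci]})
            if band != "Total":
                recs.append({"measure": "RP", "band": band, "channel": ch,
                             "value": bb.rp[bi, ci]})
    pd.DataFrame(recs).to_csv(outdir / "broadband.csv", index=False,
                              float_format="%.10g")
    written["broadband"] = outdir / "broadband.csv"

    coh = b.coherence
    labels = list(coh.channel_labels)
    n_ch = len(labels)
    iu = np.triu_indices(n_ch, k=1)
    recs = []
    for k, f in enumerate(coh.grid.display_labels_hz):
        recs.append(pd.DataFrame({
            "frequency_hz": f,
            "channel_i": [labels[i] for i in iu[0]],
            "channel_j": [labels[j] for j in iu[1]],
            "coherence": coh.coh[k][iu],
            "phase_rad": coh.phase[k][iu],
        }))
    pd.concat(recs, ignore_index=True).to_csv(
        outdir / "coherence.csv", index=False, float_format="%.10g")
    written["coherence"] = outdir / "coherence.csv"

    if b.source is not None:
        s = b.source
        n_vox = s.power.shape[0]
        df = pd.DataFrame({
            "voxel": np.repeat(np.arange(n_vox), s.grid.n_bins),
            "x": np.repeat(s.voxel_xyz[:, 0], s.grid.n_bins),
            "y": np.repeat(s.voxel_xyz[:, 1], s.grid.n_bins),
            "z_coord": np.repeat(s.voxel_xyz[:, 2], s.grid.n_bins),
            "frequency_hz": np.tile(s.grid.display_labels_hz, n_vox),
            "power": s.power.ravel(),
        })
        if b.z_source is not None:
            df["z"] = b.z_source.z.ravel()
        df.to_csv(outdir / "sources.csv", index=False, float_format="%.10g")
        written["sources"] = outdir / "sources.csv"

    summary = dict(b.provenance)
    if b.threshold is not None:
        summary["threshold"] = {"alpha": b.threshold.alpha,
                                "m": b.threshold.m,
                                "value": b.threshold.value,
                                "method": b.threshold.method}
    if b.gsf is not None:
        summary["gsf_log10"] = b.gsf.log10_value
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    written["provenance"] = outdir / "provenance.json"
    return written


def topographic_grid(values: np.ndarray, montage: Montage,
                     n: int = 64, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted scalp map on an azimuthal projection.

    Electrodes are projected to the plane by azimuthal equidistant
    projection (Cz at the origin, radius = polar angle); values are
    interpolated on an n-by-n grid covering the head circle (NaN outside).
    Deterministic: the same inputs always produce the same grid.
    """
    values = np.asarray(values, dtype=float)
    pos = montage.positions
    theta = np.arccos(np.clip(pos[:, 2], -1.0, 1.0))
    az = np.arctan2(pos[:, 1], pos[:, 0])
    px, py = theta * np.cos(az), theta * np.sin(az)
    rmax = float(theta.max()) * 1.05
    axis = np.linspace(-rmax, rmax, n)
    gx, gy = np.meshgrid(axis, axis)
    out = np.full((n, n), np.nan)
    inside = gx ** 2 + gy ** 2 <= rmax ** 2
    d2 = ((gx[inside][:, None] - px[None, :]) ** 2
          + (gy[inside][:, None] - py[None, :]) ** 2)
    exact = d2 < 1e-12
    w = 1.0 / np.maximum(d2, 1e-12) ** (power / 2.0)
    w[exact.any(axis=1)] = exact[exact.any(axis=1)].astype(float)
    out[inside] = (w @ values) / w.sum(axis=1)
    return out


def plot_topomap(values: np.ndarray, montage: Montage, path,
                 title: str = "", n: int = 64) -> None:
    """Static topographic map with the bipolar palette (blue deficit,
    red excess) centered on zero."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = topographic_grid(values, montage, n=n)
    lim = np.nanmax(np.abs(grid)) or 1.0
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(grid, origin="lower", cmap="RdBu_r", vmin=-lim, vmax=lim)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    ax.axis("off")
    fig.savefig(path, dpi=100)
    plt.close(fig)
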