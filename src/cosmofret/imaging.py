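"""Synthetic TIRF-like image layer: render traces into small frame stacks
and recover them by spot detection + colocalization with mapped DNA
positions (the CoSMoS image-analysis step, forward and inverse).

The image layer is optional in the pipeline — traces may flow directly to
the analysis — but provides an end-to-end check that trace-level results
survive the imaging round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import erf

from .params import ConfigurationError, FrameTiming
from .traces import Trace, TraceSet


@dataclass
class FieldMap:
    """Sub-pixel DNA spot coordinates in a small imaging field."""

    shape: Tuple[int, int] = (64, 64)
    positions: dict = field(default_factory=dict)   # dna_id -> (x, y)
    fiducials: List[Tuple[float, float]] = field(default_factory=list)

    def validate(self, psf_sigma: float) -> None:
        h, w = self.shape
        pts = np.array(list(self.positions.values()), dtype=float)
        if len(pts) == 0:
            return
        if (pts < 0).any() or (pts[:, 0] >= w).any() or (pts[:, 1] >= h).any():
            raise ConfigurationError("spot coordinates outside the field")
        if len(pts) > 1:
            d = np.sqrt(((pts[None, :, :] - pts[:, None, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            if d.min() <= 4.0 * psf_sigma:
                raise ConfigurationError(
                    "DNA spots closer than 4 x psf_sigma")

    @classmethod
    def random(cls, n: int, shape=(64, 64), psf_sigma: float = 1.2,
               rng_seed: int = 0, margin: float = 6.0,
               dna_ids: Optional[Sequence[int]] = None) -> "FieldMap":
        """Place n spots uniformly with minimum spacing > 4 sigma."""
        rng = np.random.default_rng(rng_seed)
        h, w = shape
        pts: List[Tuple[float, float]] = []
        guard = 0
        while len(pts) < n:
            guard += 1
            if guard > 100000:
                raise ConfigurationError("field too crowded for n spots")
            x = margin + rng.random() * (w - 2 * margin)
            y = margin + rng.random() * (h - 2 * margin)
            if all((x - px) ** 2 + (y - py) ** 2 > (4.0 * psf_sigma + 0.5) ** 2
                   for px, py in pts):
                pts.append((x, y))
        ids = list(dna_ids) if dna_ids is not None else list(range(n))
        fm = cls(shape=shape, positions=dict(zip(ids, pts)))
        fm.validate(psf_sigma)
        return fm

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [(i, x, y) for i, (x, y) in self.positions.items()],
            columns=["dna_id", "x", "y"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, shape=(64, 64)) -> "FieldMap":
        df = pd.read_csv(path)
        return cls(shape=shape, positions={
            int(r.dna_id): (float(r.x), float(r.y)) for r in df.itertuples()})


@dataclass
class MovieStack:
    """Frames indexed by (cycle, frame_kind). frames has shape
    (2 * n_cycles, H, W); even indices donor-excited, odd acceptor-excited.
    Donor-excited frames are rendered per emission channel (Dem/Aem) in
    ``donor_aem`` to keep the dual-view split."""

    frames: np.ndarray          # donor-excited: D_em view; acceptor-excited: A_em
    donor_aem: np.ndarray       # A_em view on donor-excited frames (dual view)
    timing: FrameTiming
    noise_sd: float

    @property
    def n_cycles(self) -> int:
        return self.frames.shape[0] // 2

    def save_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.frames.astype(np.float32))


def _gauss_spot(shape, x0: float, y0: float, sigma: float,
                flux: float) -> np.ndarray:
    """Integrated 2-D Gaussian: pixel (i, j) receives the PSF mass inside
    the unit pixel, so the image sums to ~flux."""
    h, w = shape
    xs = np.arange(w)
    ys = np.arange(h)
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((xs + 1 - x0) / s) - erf((xs - x0) / s))
    fy = 0.5 * (erf((ys + 1 - y0) / s) - erf((ys - y0) / s))
    return flux * np.outer(fy, fx)


def render_movie(traceset: TraceSet, fieldmap: FieldMap,
                 psf_sigma: float = 1.2, rng_seed: int = 0,
                 pixel_noise_sd: Optional[float] = None) -> MovieStack:
    """Render a TraceSet into a synthetic frame stack.

    Each spot is an integrated 2-D Gaussian whose total flux equals the
    trace intensity of that frame; per-pixel Gaussian noise is added.
    Unmapped dna_ids raise.
    """
    for tr in traceset:
        if tr.dna_id not in fieldmap.positions:
            raise ConfigurationError(f"dna_id {tr.dna_id} not in field map")
    timing = traceset.timing
    n = timing.n_cycles
    h, w = fieldmap.shape
    if pixel_noise_sd is None:
        # spread the per-frame background over the PSF footprint
        pixel_noise_sd = traceset.phys.background_sd / (4.0 * psf_sigma)
    frames = np.zeros((2 * n, h, w))
    donor_aem = np.zeros((n, h, w))
    for tr in traceset:
        x0, y0 = fieldmap.positions[tr.dna_id]
        for i in range(n):
            if tr.I_Dex_Dem[i] != 0:
                frames[2 * i] += _gauss_spot((h, w), x0, y0, psf_sigma,
                                             tr.I_Dex_Dem[i])
            if tr.I_Dex_Aem[i] != 0:
                donor_aem[i] += _gauss_spot((h, w), x0, y0, psf_sigma,
                                            tr.I_Dex_Aem[i])
            if tr.I_Aex_Aem[i] != 0:
                frames[2 * i + 1] += _gauss_spot((h, w), x0, y0, psf_sigma,
                                                 tr.I_Aex_Aem[i])
    if pixel_noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        frames = frames + rng.normal(0.0, pixel_noise_sd, frames.shape)
        donor_aem = donor_aem + rng.normal(0.0, pixel_noise_sd,
                                           donor_aem.shape)
    return MovieStack(frames=frames, donor_aem=donor_aem, timing=timing,
                      noise_sd=pixel_noise_sd)


def detect_spots(frame: np.ndarray, threshold_sd: float,
                 noise_sd: Optional[float] = None,
                 psf_sigma: float = 1.2) -> List[Tuple[float, float, float]]:
    """Local-maximum spot candidates above threshold, refined to sub-pixel
    centroids; duplicate detections within 2 sigma are merged.

    Returns (x, y, flux) triplets; flux is the background-free sum in a
    +-3 sigma box.
    """
    frame = np.asarray(frame, dtype=float)
    if noise_sd is None:
        noise_sd = float(np.median(np.abs(frame - np.median(frame))) / 0.6745)
    if not np.isfinite(threshold_sd):
        return []
    sm = ndimage.gaussian_filter(frame, psf_sigma)
    # matched-filter noise scale: smoothing reduces sigma by ~1/(2 sigma sqrt(pi))
    sm_sd = noise_sd / (2.0 * psf_sigma * np.sqrt(np.pi))
    maxed = ndimage.maximum_filter(sm, size=max(3, int(2 * psf_sigma) | 1))
    cand = np.argwhere((sm == maxed) & (sm > threshold_sd * sm_sd))
    out: List[Tuple[float, float, float]] = []
    half = max(3, int(np.ceil(3 * psf_sigma)))
    h, w = frame.shape
    for cy, cx in cand:
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        patch = frame[y0:y1, x0:x1]
        flux = float(patch.sum())
        weights = np.clip(patch, 0.0, None)
        if weights.sum() <= 0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        x_c = float((weights * (xx + 0.5)).sum() / weights.sum())
        y_c = float((weights * (yy + 0.5)).sum() / weights.sum())
        if any((x_c - px) ** 2 + (y_c - py) ** 2 < (2 * psf_sigma) ** 2
               for px, py, _ in out):
            continue
        out.append((x_c, y_c, flux))
    return out


def colocalize_and_extract(movie: MovieStack, fieldmap: FieldMap,
                           radius_px: float = 2.0,
                           psf_sigma: float = 1.2) -> TraceSet:
    """Recover per-DNA per-frame intensities by integrating a +-3 sigma box
    around each mapped DNA position (both emission views of donor-excited
    frames and the acceptor-excited frames).

    A detection flag per frame (spot within ``radius_px`` of the DNA) is
    implied by thresholding downstream; extraction itself is position-
    driven, as in mapped-spot CoSMoS analysis.
    """
    if radius_px <= 0:
        raise ConfigurationError("radius_px must be positive")
    timing = movie.timing
    n = timing.n_cycles
    half = max(3, int(np.ceil(3 * psf_sigma)))
    h, w = movie.frames.shape[1:]
    traces = []
    for dna_id, (x0, y0) in sorted(fieldmap.positions.items()):
        cx, cy = int(round(x0)), int(round(y0))
        ys = slice(max(0, cy - half), min(h, cy + half + 1))
        xs = slice(max(0, cx - half), min(w, cx + half + 1))
        dem = movie.frames[0::2, ys, xs].sum(axis=(1, 2))
        aem = movie.donor_aem[:, ys, xs].sum(axis=(1, 2))
        acc = movie.frames[1::2, ys, xs].sum(axis=(1, 2))
        traces.append(Trace(
            dna_id=dna_id,
            donor_t=timing.donor_frame_starts(),
            acceptor_t=timing.acceptor_frame_starts(),
            I_Dex_Dem=dem, I_Dex_Aem=aem, I_Aex_Aem=acc))
    from .params import ExperimentDesign, PhotophysicsParams

    return TraceSet(traces, timing, PhotophysicsParams(),
                    ExperimentDesign(n_dna=max(1, len(traces))))
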