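"""Atomic-energy structure assessment: smoothing, rescaling, correlation.

Per-atom Hartree-Fock energies (nuclear-charge normalized, valence
functions only) are noisy at the single-atom level; the pipeline smooths
them along the chain with a Savitzky-Golay filter, linearly rescales them
onto the pLDDT confidence range (with clipping at the structure's own
min/max pLDDT), and reports Pearson/Spearman correlations against the
confidence track and against a neighbour-count baseline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from scipy.spatial import cKDTree
from scipy.stats import pearsonr, spearmanr

from .structure import AtomicStructure

logger = logging.getLogger(__name__)

__all__ = ["ScoreTrack", "smooth_energies", "rescale_clip",
           "neighbour_count_track", "compare_tracks", "score_pipeline"]


@dataclass
class ScoreTrack:
    """Per-atom values aligned to structure (file) order."""

    values: np.ndarray
    kind: str                       # raw_energy | smoothed | rescaled |
                                    # plddt | neighbour_count
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def smooth_energies(track: ScoreTrack, window: int = 150,
                    polyorder: int = 3) -> ScoreTrack:
    """Savitzky-Golay smoothing of the per-atom sequence in chain order.

    The window is adjusted to the nearest odd value and shrunk (with a
    warning) if it exceeds the track length; endpoints use the filter's
    polynomial-interpolation boundary treatment.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    n = len(track.values)
    w = min(window, n)
    if w < window:
        logger.warning("smoothing window %d shrunk to track length %d",
                       window, w)
    if w % 2 == 0:
        w -= 1
    p = min(polyorder, w - 1)
    sm = savgol_filter(track.values, window_length=w, polyorder=p,
                       mode="interp")
    return ScoreTrack(sm, "smoothed",
                      {**track.parameters, "window": w, "polyorder": p})


def rescale_clip(track: ScoreTrack, scale: float = 15.0,
                 offset: float | None = None,
                 clip: tuple[float, float] = (0.0, 100.0),
                 match_track: ScoreTrack | None = None) -> ScoreTrack:
    """v -> clip(scale * v + offset), mapping energies onto the pLDDT range.

    If ``offset`` is None it is auto-fitted so the track median matches the
    median of ``match_track`` (reproducible surrogate for structure-specific
    offsets).  ``clip`` defaults to [0, 100]; pass the structure's own
    min/max pLDDT to match its observed range.
    """
    lo, hi = clip
    if not lo < hi:
        raise ValueError("clip bounds must satisfy lo < hi")
    if offset is None:
        target = (float(np.median(match_track.values))
                  if match_track is not None else 0.5 * (lo + hi))
        offset = target - scale * float(np.median(track.values))
    v = np.clip(scale * track.values + offset, lo, hi)
    return ScoreTrack(v, "rescaled",
                      {**track.parameters, "scale": scale, "offset": offset,
                       "clip": (lo, hi)})


def neighbour_count_track(structure: AtomicStructure,
                          radius: float = 8.0) -> ScoreTrack:
    """Per-atom count of non-hydrogen atoms within ``radius`` A (self excluded).

    The classical density heuristic used as a baseline for the quantum
    score.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = structure.coords_angstrom
    heavy = np.array([el != "H" for el in structure.elements])
    tree = cKDTree(coords[heavy])
    counts = np.array([len(tree.query_ball_point(p, radius))
                       for p in coords], dtype=float)
    counts -= heavy.astype(float)    # remove self for heavy atoms
    return ScoreTrack(counts, "neighbour_count", {"radius": radius})


def compare_tracks(a: ScoreTrack, b: ScoreTrack) -> dict:
    """Pearson/Spearman correlations and residuals between two tracks."""
    if len(a.values) != len(b.values):
        raise ValueError("tracks have different lengths")
    x, y = a.values, b.values
    out = {"n": int(len(x)), "kind_a": a.kind, "kind_b": b.kind}
    if np.std(x) == 0 or np.std(y) == 0:
        out["pearson"] = None
        out["spearman"] = None
        out["note"] = "correlation undefined: zero-variance track"
    else:
        out["pearson"] = float(pearsonr(x, y).statistic)
        out["spearman"] = float(spearmanr(x, y).statistic)
    out["residual_rms"] = float(np.sqrt(np.mean((x - y) ** 2)))
    return out


def score_pipeline(structure: AtomicStructure, energies: np.ndarray,
                   window: int = 150, polyorder: int = 3,
                   scale: float = 15.0, offset: float | None = None,
                   neighbour_radius: float = 8.0) -> dict:
    """Full assessment: smooth, rescale to the pLDDT range, correlate.

    Requires ``structure.b_factors`` to carry the confidence track.
    Returns a JSON-serializable report with all tracks and correlations.
    """
    if structure.b_factors is None:
        raise ValueError("structure has no B-factor / pLDDT column")
    plddt = ScoreTrack(structure.b_factors, "plddt")
    raw = ScoreTrack(np.asarray(energies, float), "raw_energy")
    smoothed = smooth_energies(raw, window, polyorder)
    clip = (float(plddt.values.min()), float(plddt.values.max()))
    if clip[0] == clip[1]:
        clip = (clip[0] - 0.5, clip[1] + 0.5)
    rescaled = rescale_clip(smoothed, scale=scale, offset=offset, clip=clip,
                            match_track=plddt)
    neigh = neighbour_count_track(structure, neighbour_radius)
    report = {
        "n_atoms": structure.n_atoms,
        "tracks": {
            "raw_energy": raw.values.tolist(),
            "smoothed": smoothed.values.tolist(),
            "rescaled": rescaled.values.tolist(),
            "plddt": plddt.values.tolist(),
            "neighbour_count": neigh.values.tolist(),
        },
        "parameters": rescaled.parameters,
        "energy_vs_plddt": compare_tracks(rescaled, plddt),
        "smoothed_energy_vs_plddt": compare_tracks(smoothed, plddt),
        "neighbour_vs_plddt": compare_tracks(neigh, plddt),
    }
    return report


def write_report(report: dict, json_path, tsv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=1)
    if tsv_path is not None:
        tr = report["tracks"]
        keys = ["raw_energy", "smoothed", "rescaled", "plddt",
                "neighbour_count"]
        with open(tsv_path, "w") as fh:
            fh.write("atom\t" + "\t".join(keys) + "\n")
            for i in range(report["n_atoms"]):
                fh.write(f"{i}\t" + "\t".join(f"{tr[k][i]:.6f}"
                                              for k in keys) + "\n")
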