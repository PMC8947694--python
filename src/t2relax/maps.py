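"""Image-domain T2 mapping: phantoms, voxel-wise fitting, NIfTI I/O.

A :class:`QuantMap` bundles a multi-echo magnitude stack (rows x cols x
echoes), its echo times, a boolean mask and, once fitted, S0/T2 parameter
maps.  The synthetic knee-like phantom provides a fully controlled stand-in
for acquired cartilage data: an annular band with a monotone depth-wise T2
gradient (low T2 at the bone interface, high at the surface) sampled at the
seven-echo scheme TE = 10, 20, ..., 70 ms.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .decay import add_rician_noise
from .evaluation import ErrorTable, build_error_table
from .fitters import fit_lse, fit_nclse, fit_olse

__all__ = ["QuantMap", "make_phantom", "fit_map", "compare_to_reference",
           "timing_harness", "read_stack", "write_quantmap", "PHANTOM_TES"]

#: Seven-echo acquisition scheme (ms) used by the phantom pipeline.
PHANTOM_TES = tuple(10.0 + 10.0 * k for k in range(7))

#: No-data sentinel in written parameter maps.
SENTINEL = np.nan


@dataclass
class QuantMap:
    """Multi-echo stack plus (optional) fitted parameter maps."""

    stack: np.ndarray          # rows x cols x n_echoes magnitudes
    te: np.ndarray             # echo times, ms, strictly increasing
    mask: np.ndarray           # boolean, same rows x cols
    s0_map: np.ndarray | None = None
    t2_map: np.ndarray | None = None
    sigma_map: np.ndarray | None = None
    method: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        self.te = np.asarray(self.te, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.stack.ndim != 3:
            raise ValueError("stack must be rows x cols x echoes")
        if self.stack.shape[:2] != self.mask.shape:
            raise ValueError("mask grid must match the stack")
        if len(self.te) != self.stack.shape[2]:
            raise ValueError("one echo time per stack volume required")
        if np.any(np.diff(self.te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if np.any(self.stack < 0):
            raise ValueError("magnitude stack must be non-negative")


def make_phantom(
    shape: tuple[int, int] = (64, 64),
    t2_range: tuple[float, float] = (20.0, 60.0),
    s0_level: float = 500.0,
    sigma: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[QuantMap, QuantMap]:
    """Synthetic cartilage-like phantom with depth-wise T2 stratification.

    An annular band centred in the image models a cartilage cross-section:
    T2 increases linearly from ``t2_range[0]`` at the inner (bone) interface
    to ``t2_range[1]`` at the outer (fluid) surface; S0 is uniform inside the
    band.  Seven echoes at TE = 10..70 ms are simulated, optionally corrupted
    with Rician noise of standard deviation ``sigma``.

    Returns
    -------
    (truth, noisy)
        ``truth`` carries the noise-free stack and the ground-truth
        ``s0_map``/``t2_map``; ``noisy`` carries the corrupted stack and a
        constant ``sigma_map`` inside the mask.
    """
    if shape[0] < 16 or shape[1] < 16:
        raise ValueError("phantom must be at least 16 x 16")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    r = np.hypot((yy - cy) / rows, (xx - cx) / cols)  # normalized radius
    r_in, r_out = 0.18, 0.42
    mask = (r >= r_in) & (r <= r_out)
    depth = np.clip((r - r_in) / (r_out - r_in), 0.0, 1.0)  # 0 = bone side
    t2_map = np.where(mask, t2_range[0] + (t2_range[1] - t2_range[0]) * depth, SENTINEL)
    s0_map = np.where(mask, s0_level, SENTINEL)
    te = np.asarray(PHANTOM_TES)
    clean = np.zeros((rows, cols, len(te)))
    clean[mask] = s0_level * np.exp(-te[None, :] / t2_map[mask][:, None])
    noisy = add_rician_noise(clean, sigma, rng) if sigma > 0 else clean.copy()
    truth = QuantMap(stack=clean, te=te, mask=mask, s0_map=s0_map,
                     t2_map=t2_map, method="truth")
    sigma_map = np.where(mask, float(sigma), SENTINEL)
    observed = QuantMap(stack=noisy, te=te, mask=mask, sigma_map=sigma_map,
                        meta={"sigma": float(sigma)})
    return truth, observed


def fit_map(
    map_in: QuantMap,
    method: str = "lse",
    sigma: float | np.ndarray | None = None,
    model=None,
) -> QuantMap:
    """Voxel-wise fit of the chosen estimator inside the mask.

    ``method`` is one of ``'lse'``, ``'olse'``, ``'nclse'`` or ``'nn'``.
    For ``'nclse'`` a noise level is required: a scalar, a per-voxel map, or
    (by default) the ``sigma_map`` carried by the input.  For ``'nn'`` a
    trained :class:`~t2relax.network.T2Network` must be supplied.  Out-of-mask
    voxels hold NaN; fallback voxel counts are recorded in ``meta``.
    """
    known = {"lse", "olse", "nclse", "nn"}
    if method not in known:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(known)}")
    if not map_in.mask.any():
        raise ValueError("mask is empty")
    if map_in.stack.shape[2] < 2:
        raise ValueError("need at least 2 echoes")
    rows, cols, _ = map_in.stack.shape
    s0_map = np.full((rows, cols), SENTINEL)
    t2_map = np.full((rows, cols), SENTINEL)
    idx = np.argwhere(map_in.mask)
    te = map_in.te
    n_fallback = 0

    if method == "nn":
        if model is None:
            raise ValueError("method 'nn' requires a trained network")
        from .synth import MAX_N, PAD

        mags = map_in.stack[map_in.mask]
        n_e = len(te)
        x = np.full((len(mags), 2 * MAX_N), PAD, dtype=np.float32)
        x[:, :n_e] = mags
        x[:, MAX_N:MAX_N + n_e] = te
        pred = model.forward(x)
        s0_map[map_in.mask] = pred[:, 0]
        t2_map[map_in.mask] = pred[:, 1]
    else:
        if method == "nclse":
            if sigma is None:
                if map_in.sigma_map is None:
                    raise ValueError("method 'nclse' needs sigma (scalar, map, or sigma_map)")
                sigma_arr = map_in.sigma_map
            else:
                sigma_arr = np.broadcast_to(np.asarray(sigma, dtype=float),
                                            (rows, cols))
        for i, j in idx:
            train = (te, map_in.stack[i, j])
            if method == "lse":
                r = fit_lse(train)
            elif method == "olse":
                r = fit_olse(train)
            else:
                r = fit_nclse(train, float(sigma_arr[i, j]))
            s0_map[i, j] = r.s0_hat
            t2_map[i, j] = r.t2_hat
            n_fallback += int(r.fallback)

    return replace(
        map_in, s0_map=s0_map, t2_map=t2_map, method=method,
        meta={**map_in.meta, "n_fallback": n_fallback, "n_fitted": len(idx)},
    )


def compare_to_reference(
    low_snr_fit: QuantMap | list[QuantMap],
    reference_fit: QuantMap | list[QuantMap],
    snr_label: float = 0.0,
) -> ErrorTable:
    """Voxel-wise RQE/ARQE of a fit against a reference map.

    The in-situ protocol: the reference is the traditional-LSE fit of the
    high-SNR acquisition, and voxel-wise comparisons are concatenated across
    specimens (pass lists to concatenate).  Masks must match pairwise.
    """
    fits = low_snr_fit if isinstance(low_snr_fit, list) else [low_snr_fit]
    refs = reference_fit if isinstance(reference_fit, list) else [reference_fit]
    if len(fits) != len(refs):
        raise ValueError("need one reference per fitted map")
    preds, targets = [], []
    for f, r in zip(fits, refs):
        if f.mask.shape != r.mask.shape or not np.array_equal(f.mask, r.mask):
            raise ValueError("fit and reference masks do not match")
        preds.append(f.t2_map[f.mask])
        targets.append(r.t2_map[r.mask])
    method = fits[0].method or "fit"
    return build_error_table(
        {method: np.concatenate(preds)}, np.concatenate(targets), snr_label
    )


def timing_harness(
    map_in: QuantMap,
    methods: dict[str, dict],
    repeats: int = 3,
) -> dict[str, float]:
    """Mean wall-clock seconds per method over ``repeats`` runs.

    ``methods`` maps a method name to keyword arguments for :func:`fit_map`
    (e.g. ``{'nclse': {'sigma': 12.0}, 'nn': {'model': net}}``).  Timings are
    reported for information only; they depend entirely on hardware.
    """
    if repeats < 1:
        raise ValueError("need at least one repeat")
    out = {}
    for name, kwargs in methods.items():
        times = []
        for _ in range(repeats):
            t0 = time.perf_counter()
            fit_map(map_in, method=name, **kwargs)
            times.append(time.perf_counter() - t0)
        out[name] = float(np.mean(times))
    return out


# ---- NIfTI I/O -------------------------------------------------------------


def read_stack(stack_path, tes_path, mask_path=None) -> QuantMap:
    """Load a 4D NIfTI echo stack, JSON echo times, and optional mask."""
    img = nib.load(str(stack_path))
    stack = np.asarray(img.dataobj, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a rows x cols x echoes volume")
    te = np.asarray(json.loads(Path(tes_path).read_text()), dtype=float)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(stack.shape[:2], dtype=bool)
    qm = QuantMap(stack=stack, te=te, mask=mask)
    qm.meta["affine"] = img.affine
    return qm


def write_quantmap(qmap: QuantMap, out_dir) -> dict[str, Path]:
    """Write T2/S0 maps (NIfTI), echo times (JSON) and a per-voxel CSV report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = qmap.meta.get("affine", np.eye(4))
    paths = {}
    for name, arr in (("T2", qmap.t2_map), ("S0", qmap.s0_map)):
        if arr is None:
            continue
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.float64), affine), str(p))
        paths[name] = p
    te_path = out_dir / "tes.json"
    te_path.write_text(json.dumps(list(map(float, qmap.te))))
    paths["tes"] = te_path
    if qmap.t2_map is not None:
        import pandas as pd

        ii, jj = np.nonzero(qmap.mask)
        report = pd.DataFrame({
            "row": ii, "col": jj,
            "s0_hat": qmap.s0_map[ii, jj] if qmap.s0_map is not None else np.nan,
            "t2_hat": qmap.t2_map[ii, jj],
            "method": qmap.method,
        })
        rp = out_dir / "report.csv"
        report.to_csv(rp, index=False)
        paths["report"] = rp
    return paths
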