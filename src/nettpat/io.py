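"""HDF5 containers and YAML configuration for the reconstruction pipeline.

All on-disk artifacts are HDF5 files written with ``track_times=False`` so a
rerun with identical inputs produces bit-identical files:

* model container — masked-operator SVD factors, threshold, mask, geometry;
* dataset container — phantoms ``x``, basic reconstructions ``h``, noise, seed;
* regularizer checkpoint — network weights plus architecture attributes;
* reconstruction container — iterate, objective trace, solver settings.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .forward import KBParams, SystemMatrix, TruncatedOperator, \
    assemble_system_matrix, truncate_operator
from .geometry import GridSpec, MaskSpec, SensorGeometry, mask_indicator
from .phantoms import Dataset, RingPhantomConfig
from .regularizer import LearnedRegularizer, NetworkSpec
from .solver import ReconResult, SolverConfig

__all__ = [
    "load_config",
    "build_operator_from_config",
    "save_model", "load_model",
    "save_dataset", "load_dataset",
    "save_regularizer", "load_regularizer",
    "save_recon", "load_recon",
    "export_png",
]


def _write(group, name, data):
    group.create_dataset(name, data=np.asarray(data), track_times=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def geometry_from_config(cfg: dict) -> tuple[GridSpec, SensorGeometry, MaskSpec]:
    grid = GridSpec(N=int(cfg.get("grid", {}).get("N", 128)))
    sens = cfg.get("sensors", {})
    geom = SensorGeometry(Ns=int(sens.get("Ns", 150)), Nt=int(sens.get("Nt", 128)))
    m = cfg.get("mask", {})
    mask = MaskSpec(width=float(m.get("width", 0.34)),
                    orientation=m.get("orientation", "main"))
    return grid, geom, mask


def kb_from_config(cfg: dict, grid: GridSpec) -> KBParams:
    kb = cfg.get("kb", {})
    return KBParams.for_grid(grid, m=int(kb.get("m", 2)),
                             gamma=float(kb.get("gamma", 3.0)),
                             radius_in_pixels=float(kb.get("radius_in_pixels", 2.0)))


def build_operator_from_config(cfg: dict) -> tuple[TruncatedOperator, GridSpec,
                                                   SensorGeometry, MaskSpec, KBParams]:
    """Assemble the masked, truncated forward operator described by a config."""
    grid, geom, mask = geometry_from_config(cfg)
    kb = kb_from_config(cfg, grid)
    W = assemble_system_matrix(grid, geom, kb,
                               max_grid_size=int(cfg.get("max_grid_size", 192)))
    trunc = cfg.get("truncation", {})
    op = truncate_operator(W, mask_indicator(grid, mask),
                           sigma_star=float(trunc.get("sigma_star", 1e-3)),
                           relative=bool(trunc.get("relative", True)))
    return op, grid, geom, mask, kb


# -- model container --------------------------------------------------------

def save_model(path: str | Path, op: TruncatedOperator, grid: GridSpec,
               geom: SensorGeometry, mask: MaskSpec, kb: KBParams,
               store_W: SystemMatrix | None = None) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        for name, arr in (("U", op.U), ("s", op.s), ("Vt", op.Vt),
                          ("maskvec", op.maskvec)):
            _write(f, name, arr)
        if store_W is not None:
            _write(f, "W", store_W.W)
        f.attrs.update({
            "sigma_star": op.sigma_star, "N": grid.N, "Ns": geom.Ns,
            "Nt": geom.Nt, "angular_offset": geom.angular_offset,
            "mask_width": mask.width, "mask_orientation": mask.orientation,
            "kb_m": kb.m, "kb_gamma": kb.gamma, "kb_R": kb.R,
        })


def load_model(path: str | Path) -> tuple[TruncatedOperator, GridSpec,
                                          SensorGeometry, MaskSpec, KBParams]:
    with h5py.File(path, "r") as f:
        a = dict(f.attrs)
        op = TruncatedOperator(U=f["U"][()], s=f["s"][()], Vt=f["Vt"][()],
                               sigma_star=float(a["sigma_star"]),
                               maskvec=f["maskvec"][()])
        grid = GridSpec(N=int(a["N"]))
        geom = SensorGeometry(Ns=int(a["Ns"]), Nt=int(a["Nt"]),
                              angular_offset=float(a["angular_offset"]))
        mask = MaskSpec(width=float(a["mask_width"]),
                        orientation=str(a["mask_orientation"]))
        kb = KBParams(m=int(a["kb_m"]), gamma=float(a["kb_gamma"]),
                      R=float(a["kb_R"]))
    return op, grid, geom, mask, kb


# -- dataset container ------------------------------------------------------

def save_dataset(path: str | Path, data: Dataset) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        _write(f, "x", data.x)
        _write(f, "h", data.h)
        f.attrs.update({"sigma": data.sigma, "seed": data.seed})


def load_dataset(path: str | Path) -> Dataset:
    with h5py.File(path, "r") as f:
        return Dataset(x=f["x"][()], h=f["h"][()],
                       sigma=float(f.attrs["sigma"]), seed=int(f.attrs["seed"]))


# -- regularizer checkpoint --------------------------------------------------

def save_regularizer(path: str | Path, reg: LearnedRegularizer,
                     spec: NetworkSpec) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        g = f.create_group("params")
        for k, v in sorted(reg.net.get_params().items()):
            _write(g, k, v)
        f.attrs.update({
            "depth": spec.depth, "base_channels": spec.base_channels,
            "kernel_size": spec.kernel_size, "residual": spec.residual,
            "dtype": spec.dtype, "beta": reg.beta, "eps": reg.eps,
        })


def load_regularizer(path: str | Path) -> tuple[LearnedRegularizer, NetworkSpec]:
    with h5py.File(path, "r") as f:
        a = dict(f.attrs)
        spec = NetworkSpec(depth=int(a["depth"]),
                           base_channels=int(a["base_channels"]),
                           kernel_size=int(a["kernel_size"]),
                           residual=bool(a["residual"]), dtype=str(a["dtype"]))
        net = spec.build()
        net.set_params({k: v[()] for k, v in f["params"].items()})
        reg = LearnedRegularizer(net=net, beta=float(a["beta"]),
                                 eps=float(a["eps"]))
    return reg, spec


# -- reconstruction container -------------------------------------------------

def save_recon(path: str | Path, res: ReconResult) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        _write(f, "x", res.x)
        _write(f, "objective_trace", res.objective_trace)
        c = res.config
        f.attrs.update({"alpha": c.alpha, "s": c.s, "Niter": c.Niter,
                        "init": c.init, "reuse_inverse": c.reuse_inverse,
                        "data_fidelity": res.data_fidelity,
                        "regularizer": res.regularizer})


def load_recon(path: str | Path) -> ReconResult:
    with h5py.File(path, "r") as f:
        a = dict(f.attrs)
        cfg = SolverConfig(alpha=float(a["alpha"]), s=float(a["s"]),
                           Niter=int(a["Niter"]), init=str(a["init"]),
                           reuse_inverse=bool(a["reuse_inverse"]))
        return ReconResult(x=f["x"][()], objective_trace=f["objective_trace"][()],
                           data_fidelity=float(a["data_fidelity"]),
                           regularizer=float(a["regularizer"]), config=cfg)


def export_png(path: str | Path, x: np.ndarray, vmin: float = 0.0,
               vmax: float = 1.0) -> None:
    """Write a flat coefficient vector as an 8-bit grayscale PNG."""
    from PIL import Image

    x = np.asarray(x, dtype=np.float64)
    N = int(round(np.sqrt(x.size)))
    img = np.clip((x.reshape(N, N) - vmin) / (vmax - vmin), 0.0, 1.0)
    Image.fromarray((img * 255).astype(np.uint8), mode="L").save(path)
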