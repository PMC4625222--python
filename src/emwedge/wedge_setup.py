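"""Wedge geometry, transmural cell-type layering and experiment presets.

The computational domain is a structured hexahedral block of left
ventricular wall: 9 x 9 x 9 mm in the normal condition and
13 x 9 x 9 mm in heart failure (hypertrophic wall), discretized at
dx = 0.5 mm.  The transmural axis is x (endocardium at x = 0), fibers
run along y.  Cell types are layered transmurally as 12% endo / 60% M
/ 28% epi, with layer boundaries aligned to element faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["WedgeSpec", "WedgeMesh", "build_wedge", "layer_element_counts",
           "preset_configs", "write_vtk", "CONDITIONS"]

CONDITIONS = ("nf", "hf", "hf_case2")

CELL_TYPE_CODES = {"endo": 0, "M": 1, "epi": 2}
CELL_TYPE_NAMES = {v: k for k, v in CELL_TYPE_CODES.items()}


@dataclass
class WedgeSpec:
    """Geometry + condition description of one wedge experiment."""

    condition: str = "nf"
    dx: float = 0.5                      # mm
    depth: float | None = None           # transmural extent, mm
    width: float = 9.0                   # fiber (y) extent, mm
    height: float = 9.0                  # z extent, mm
    fractions: tuple = (0.12, 0.60, 0.28)  # endo / M / epi

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.depth is None:
            self.depth = 9.0 if self.condition == "nf" else 13.0
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("layer fractions must sum to 1")
        for dim in (self.depth, self.width, self.height):
            n = dim / self.dx
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"dimension {dim} mm is not a multiple of dx={self.dx} mm")


def layer_element_counts(nx: int, fractions=(0.12, 0.60, 0.28)):
    """Element counts (endo, M, epi) along the transmural axis.

    Endo and epi counts are rounded to the nearest integer and the M
    layer absorbs the remainder, which preserves the 60% midwall
    plateau (18 elements -> 2/11/5).
    """
    n_endo = int(round(fractions[0] * nx))
    n_epi = int(round(fractions[2] * nx))
    n_m = nx - n_endo - n_epi
    if min(n_endo, n_m, n_epi) < 1:
        raise ValueError(f"mesh too coarse for three layers (nx={nx})")
    return n_endo, n_m, n_epi


@dataclass
class WedgeMesh:
    """Structured trilinear hexahedral mesh with fibers and labels."""

    nodes: np.ndarray          # (n_nodes, 3) coordinates, mm
    elems: np.ndarray          # (n_elems, 8) connectivity, VTK ordering
    shape: tuple               # (nx, ny, nz) element counts
    dx: float
    fibers: np.ndarray         # (n_elems, 3) unit fiber direction f0
    node_cell_type: np.ndarray  # (n_nodes,) codes 0/1/2 = endo/M/epi
    face_nodes: dict = field(default_factory=dict)  # tag -> node indices

    @property
    def n_nodes(self):
        return self.nodes.shape[0]

    @property
    def n_elems(self):
        return self.elems.shape[0]

    @property
    def extent(self):
        return self.nodes.max(axis=0) - self.nodes.min(axis=0)

    def node_types_named(self):
        return np.array([CELL_TYPE_NAMES[c] for c in self.node_cell_type])


def build_wedge(spec: WedgeSpec) -> WedgeMesh:
    """Structured wedge mesh with transmural layering and face tags.

    Mechanics boundary conditions (zero normal displacement) apply on
    the faces tagged ``x0``, ``y0``, ``z0`` and ``zmax``; the
    electrical stimulus region is the endocardial face ``x0``.
    """
    nx = int(round(spec.depth / spec.dx))
    ny = int(round(spec.width / spec.dx))
    nz = int(round(spec.height / spec.dx))

    xs = np.linspace(0.0, spec.depth, nx + 1)
    ys = np.linspace(0.0, spec.width, ny + 1)
    zs = np.linspace(0.0, spec.height, nz + 1)
    # node index (i, j, k) -> i + (nx+1)*(j + (ny+1)*k)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(order="F"), Y.ravel(order="F"),
                             Z.ravel(order="F")])

    def nid(i, j, k):
        return i + (nx + 1) * (j + (ny + 1) * k)

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ii, jj, kk = ii.ravel(order="F"), jj.ravel(order="F"), kk.ravel(order="F")
    elems = np.column_stack([
        nid(ii, jj, kk), nid(ii + 1, jj, kk),
        nid(ii + 1, jj + 1, kk), nid(ii, jj + 1, kk),
        nid(ii, jj, kk + 1), nid(ii + 1, jj, kk + 1),
        nid(ii + 1, jj + 1, kk + 1), nid(ii, jj + 1, kk + 1),
    ]).astype(np.int64)

    fibers = np.tile(np.array([0.0, 1.0, 0.0]), (elems.shape[0], 1))

    # node label by transmural index; interface nodes take the
    # endocardial-side label (meshes too coarse for three layers are
    # labelled all-M; they only serve mechanics-only runs)
    itrans = np.rint(nodes[:, 0] / spec.dx).astype(int)
    try:
        n_endo, n_m, n_epi = layer_element_counts(nx, spec.fractions)
        node_type = np.full(nodes.shape[0], CELL_TYPE_CODES["epi"])
        node_type[itrans <= n_endo + n_m] = CELL_TYPE_CODES["M"]
        node_type[itrans <= n_endo] = CELL_TYPE_CODES["endo"]
    except ValueError:
        node_type = np.full(nodes.shape[0], CELL_TYPE_CODES["M"])

    tol = 1e-9
    face_nodes = {
        "x0": np.flatnonzero(nodes[:, 0] < tol),
        "xmax": np.flatnonzero(nodes[:, 0] > spec.depth - tol),
        "y0": np.flatnonzero(nodes[:, 1] < tol),
        "ymax": np.flatnonzero(nodes[:, 1] > spec.width - tol),
        "z0": np.flatnonzero(nodes[:, 2] < tol),
        "zmax": np.flatnonzero(nodes[:, 2] > spec.height - tol),
    }
    return WedgeMesh(nodes=nodes, elems=elems, shape=(nx, ny, nz),
                     dx=spec.dx, fibers=fibers, node_cell_type=node_type,
                     face_nodes=face_nodes)


def center_probe_nodes(mesh: WedgeMesh):
    """Node indices at the centers of the endocardial (x0) and
    epicardial (xmax) faces — the electrogram electrode positions."""
    out = {}
    for tag in ("x0", "xmax"):
        ids = mesh.face_nodes[tag]
        pts = mesh.nodes[ids][:, 1:]
        ctr = 0.5 * (pts.max(axis=0) + pts.min(axis=0))
        out[tag] = int(ids[np.argmin(((pts - ctr) ** 2).sum(axis=1))])
    return out["x0"], out["xmax"]


# ---------------------------------------------------------------------------
# experiment presets
# ---------------------------------------------------------------------------

# passive Holzapfel-Ogden defaults (transversely isotropic reduction)
HO_DEFAULTS = {"a": 0.496, "b": 7.209, "a_f": 15.193, "b_f": 20.417}


def preset_configs(condition: str) -> dict:
    """Complete, serializable configuration of one experiment arm.

    nf: 9 mm depth, nominal conductivities, nominal passive stiffness.
    hf: 13 mm depth, conductivities x0.7, stiffness x5, HF cells.
    hf_case2: as hf but with control (x1) passive stiffness.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    hf_cells = condition in ("hf", "hf_case2")
    cfg = {
        "condition": condition,
        "geometry": {
            "depth_mm": 9.0 if condition == "nf" else 13.0,
            "width_mm": 9.0,
            "height_mm": 9.0,
            "dx_mm": 0.5,
            "fractions": [0.12, 0.60, 0.28],
        },
        "cells": {
            "hf": hf_cells,
            "pacing_hz": 1.0,
        },
        "ep": {
            "sigma_i_f": 3.0, "sigma_i_s": 1.0,
            "sigma_e_f": 2.0, "sigma_e_s": 1.65,
            "conductivity_scale": 0.7 if hf_cells else 1.0,
            "chi": 2000.0, "cm": 1.0,
            "dt_ode": 0.05, "dt_pde": 0.05,
            "stim_amplitude": -80.0, "stim_duration": 2.0,
        },
        "mechanics": {
            **HO_DEFAULTS,
            "stiffness_scale": 5.0 if condition == "hf" else 1.0,
            "Ta_max": 50.0,
            "bulk_modulus": 10000.0,
            "n_inc": 10,
            "dt_mech": 1.0,
        },
        "T_ms": 1000.0,
    }
    return cfg


def save_config(cfg: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def spec_from_config(cfg: dict) -> WedgeSpec:
    g = cfg["geometry"]
    return WedgeSpec(condition=cfg["condition"], dx=g["dx_mm"],
                     depth=g["depth_mm"], width=g["width_mm"],
                     height=g["height_mm"],
                     fractions=tuple(g["fractions"]))


# ---------------------------------------------------------------------------
# minimal legacy-ASCII VTK output (structured hex meshes)
# ---------------------------------------------------------------------------

def write_vtk(path, mesh: WedgeMesh, point_data: dict | None = None,
              displacements: np.ndarray | None = None):
    """Write the mesh (optionally deformed) with nodal scalar fields as
    a legacy ASCII VTK unstructured grid."""
    pts = mesh.nodes if displacements is None else mesh.nodes + displacements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nemwedge\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, pts, fmt="%.8g")
        fh.write(f"CELLS {mesh.n_elems} {mesh.n_elems * 9}\n")
        np.savetxt(fh, np.column_stack(
            [np.full(mesh.n_elems, 8), mesh.elems]), fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_elems}\n")
        np.savetxt(fh, np.full(mesh.n_elems, 12), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(arr, float), fmt="%.8g")
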