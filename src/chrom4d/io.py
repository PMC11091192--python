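"""File formats: dense contact matrices, bedGraph, BED6, trajectories.

Conventions: all genomic coordinates are 0-based half-open (BED native).
Contact maps are dense whitespace matrices with a commented header
carrying n, bin_bp and the contact threshold; anchor sets are BED6 with
the strand column holding the orientation and the score column the
engagement probability scaled by 1000.  Trajectories round-trip through
an XYZ-like text format (one frame per block, comment line = time stamp)
and an HDF5 container.
"""

from __future__ import annotations

import json
import hashlib
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .extrusion import AnchorSet, _ORIENT_TO_STRAND, _STRAND_TO_ORIENT
from .maps import ContactMap
from .state import Conformation, Trajectory

__all__ = [
    "write_matrix", "read_matrix",
    "write_bedgraph", "read_bedgraph",
    "write_anchors_bed", "read_anchors_bed",
    "write_xyz", "read_xyz",
    "write_trajectory_h5", "read_trajectory_h5",
    "write_manifest",
]


# ----------------------------------------------------------------- matrices
def write_matrix(path, cmap: ContactMap) -> None:
    """Dense whitespace matrix with a self-describing header."""
    header = (
        f"chrom4d-matrix n={cmap.n} bin_bp={cmap.bin_bp:g} "
        f"threshold={cmap.threshold:g} n_conformations={cmap.n_conformations}"
    )
    np.savetxt(path, cmap.matrix, header=header, fmt="%.17g")


def read_matrix(path, expect_bin_bp: float | None = None) -> ContactMap:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if not first.startswith("#") or "chrom4d-matrix" not in first:
        raise ValueError(f"{path}: missing chrom4d-matrix header line")
    fields = dict(
        tok.split("=", 1) for tok in first.lstrip("#").split() if "=" in tok
    )
    for req in ("n", "bin_bp", "threshold"):
        if req not in fields:
            raise ValueError(f"{path}: header missing field {req!r}")
    m = np.loadtxt(path)
    n = int(fields["n"])
    if m.shape != (n, n):
        raise ValueError(f"{path}: matrix shape {m.shape} does not match header n={n}")
    bin_bp = float(fields["bin_bp"])
    if expect_bin_bp is not None and bin_bp != expect_bin_bp:
        raise ValueError(f"{path}: bin_bp={bin_bp} but expected {expect_bin_bp}")
    return ContactMap(
        matrix=m, bin_bp=bin_bp, threshold=float(fields["threshold"]),
        n_conformations=int(fields.get("n_conformations", 0)),
    )


# ---------------------------------------------------------------- bedGraph
def write_bedgraph(path, chrom: str, starts, ends, values) -> None:
    df = pd.DataFrame({"chrom": chrom, "start": np.asarray(starts, dtype=int),
                       "end": np.asarray(ends, dtype=int), "value": values})
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, on_overlap: str = "error") -> pd.DataFrame:
    """Read a bedGraph into (chrom, start, end, value), 0-based half-open.

    Overlapping intervals raise by default (``on_overlap="error"``) or are
    kept for downstream averaging (``"keep"``).  A file that looks 1-based
    (an interval with end == start) is rejected rather than reinterpreted.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: empty or inverted intervals (1-based input?)")
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    same = df["chrom"].shift(-1) == df["chrom"]
    overlap = same & (df["end"].shift(-1).notna()) & (df["start"].shift(-1) < df["end"])
    if overlap.any():
        if on_overlap == "error":
            raise ValueError(f"{path}: overlapping intervals detected")
        if on_overlap != "keep":
            raise ValueError(f"unknown on_overlap={on_overlap!r}")
    return df


# ------------------------------------------------------------------- BED6
def write_anchors_bed(path, anchors: AnchorSet, bin_bp: float, chrom: str = "model") -> None:
    """Anchors as BED6: strand = orientation, score = probability * 1000."""
    starts = (anchors.beads * bin_bp).astype(int)
    df = pd.DataFrame({
        "chrom": chrom,
        "start": starts,
        "end": (starts + bin_bp).astype(int),
        "name": [f"anchor{k}" for k in range(len(anchors))],
        "score": np.round(anchors.probabilities * 1000).astype(int),
        "strand": [_ORIENT_TO_STRAND[o] for o in anchors.orientations],
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def read_anchors_bed(path, bin_bp: float) -> AnchorSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"])
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: empty or inverted intervals (1-based input?)")
    beads = (df["start"] // bin_bp).astype(int).to_numpy()
    orient = np.array([_STRAND_TO_ORIENT[s] for s in df["strand"]])
    p = (df["score"] / 1000.0).clip(0, 1).to_numpy()
    return AnchorSet(beads, orient, p)


# ------------------------------------------------------------ trajectories
def write_xyz(path, traj: Trajectory) -> None:
    """XYZ-like text: per frame, a count line, a comment line with the time
    stamp and box, then one ``C x y z`` line per bead."""
    with Path(path).open("w") as fh:
        for frame in traj.frames:
            fh.write(f"{frame.n_beads}\n")
            fh.write(f"time={frame.time} box_L={frame.box_L:.17g} "
                     f"replica={traj.replica_id} interval={traj.sample_interval}\n")
            for p in frame.beads:
                fh.write(f"C {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")


def read_xyz(path) -> Trajectory:
    frames: list[Conformation] = []
    replica_id, interval = 0, 1
    with Path(path).open() as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            meta = dict(tok.split("=", 1) for tok in fh.readline().split() if "=" in tok)
            replica_id = int(meta.get("replica", 0))
            interval = int(meta.get("interval", 1))
            beads = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                beads[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            frames.append(Conformation(beads=beads, box_L=float(meta.get("box_L", 50.0)),
                                       time=int(meta.get("time", len(frames) + 1))))
    if not frames:
        raise ValueError(f"{path}: no frames")
    return Trajectory(frames=frames, replica_id=replica_id, sample_interval=interval)


def write_trajectory_h5(path, trajectories: list[Trajectory]) -> None:
    with h5py.File(path, "w") as h5:
        for traj in trajectories:
            grp = h5.create_group(f"replica_{traj.replica_id}")
            grp.attrs["sample_interval"] = traj.sample_interval
            grp.attrs["seed"] = -1 if traj.seed is None else traj.seed
            grp.attrs["box_L"] = traj.frames[0].box_L
            grp.create_dataset("positions", data=traj.positions())
            grp.create_dataset("times", data=traj.times())


def read_trajectory_h5(path) -> list[Trajectory]:
    out: list[Trajectory] = []
    with h5py.File(path, "r") as h5:
        for name in sorted(h5, key=lambda s: int(s.split("_")[1])):
            grp = h5[name]
            pos = grp["positions"][...]
            times = grp["times"][...]
            box_L = float(grp.attrs["box_L"])
            frames = [Conformation(beads=p, box_L=box_L, time=int(t))
                      for p, t in zip(pos, times)]
            seed = int(grp.attrs["seed"])
            out.append(Trajectory(frames=frames,
                                  replica_id=int(name.split("_")[1]),
                                  sample_interval=int(grp.attrs["sample_interval"]),
                                  seed=None if seed < 0 else seed))
    return out


# --------------------------------------------------------------- manifest
def write_manifest(out_dir, command: str, params: dict, inputs: list[str],
                   outputs: list[str]) -> Path:
    """One provenance manifest per CLI run (command, config hash, seeds,
    paths, timestamp)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(params, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "params": params,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
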