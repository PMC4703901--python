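"""Ion-surface association analysis on trajectory snapshots.

Two distribution modes are provided. `rdf_min_distance` histograms each
ion's minimum distance to any protein atom per frame — the natural
"association with the whole surface" statistic for an irregularly shaped
solute — and normalises it against the same statistic for uniformly placed
pseudo-ions (a seeded Monte-Carlo ideal reference), so the result reads
like a g(r): ≈1 where ions are as common as chance, >1 where they
accumulate. `rdf_site` is the textbook pair g(r) against a specific site
under the minimum-image convention, which requires a periodic box.

`residence_events` extracts gap-tolerant contiguous contact intervals
(residence times), and `compare_association` integrates two curves over a
window to quantify enrichment of one system over another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

DEFAULT_BIN_WIDTH = 0.05  # Å
DEFAULT_R_MAX = 10.0  # Å
DEFAULT_CONTACT_CUTOFF = 3.0  # Å, direct coordination
DEFAULT_GAP_TOLERANCE = 2  # frames


class TrajectoryError(ValueError):
    pass


@dataclass
class Trajectory:
    """Per-frame coordinates plus named atom selections.

    frames: (n_frames, n_atoms, 3) array in Å. groups: name -> atom index
    array. box: optional (n_frames, 3) orthorhombic box lengths. frame
    spacing (ps) is metadata used to convert residence durations to time.
    """

    frames: np.ndarray
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    box: np.ndarray | None = None
    frame_spacing_ps: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise TrajectoryError("trajectory has no frames")
        self.groups = {k: np.asarray(v, dtype=int) for k, v in self.groups.items()}
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.ndim == 1:
                self.box = np.tile(self.box, (self.n_frames, 1))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def group(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(f"no atom group named {name!r}; have {sorted(self.groups)}")


@dataclass
class RdfCurve:
    bin_edges: np.ndarray  # Å, len = n_bins + 1
    g: np.ndarray  # dimensionless (or probability density in raw mode)
    reference: str  # "mc_ideal" | "raw" | "bulk_density"
    frames_used: int
    metadata: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"r_A": self.bin_centers, "g": self.g}).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


@dataclass(frozen=True)
class ResidenceEvent:
    ion: int
    site: str
    start_frame: int
    end_frame: int  # inclusive

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_ps(self, frame_spacing_ps: float) -> float:
        return self.duration_frames * frame_spacing_ps


# ---------------------------------------------------------------------------
# I/O


def read_frames(
    path,
    format: str = "pdb",
    selections: dict[str, str] | None = None,
    frame_spacing_ps: float = 1.0,
    box: np.ndarray | None = None,
) -> Trajectory:
    """Read a multi-model PDB or XYZ file into a Trajectory.

    ``selections`` maps group names to element symbols (XYZ) or residue
    names (PDB), e.g. {"sodium": "NA", "protein": "protein"}; the special
    value "protein" selects standard amino-acid residues (PDB) or every
    atom not claimed by another selection (XYZ).
    """
    if format == "xyz":
        names, frames = read_xyz(path)
        groups = _groups_from_names(names, selections or {})
    elif format == "pdb":
        names, resnames, frames = _read_multimodel_pdb(path)
        groups = _groups_from_pdb(resnames, selections or {})
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")
    return Trajectory(frames=frames, groups=groups, box=box, frame_spacing_ps=frame_spacing_ps)


def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Plain XYZ: repeated blocks of (count, comment, atom lines)."""
    frames = []
    names0: list[str] | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        if len(block) != n:
            raise TrajectoryError(f"frame {frame_no}: expected {n} atom lines, got {len(block)}")
        names = [ln.split()[0] for ln in block]
        coords = np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
        if names0 is None:
            names0 = names
        elif names != names0:
            raise TrajectoryError(f"frame {frame_no}: atom identities differ from frame 0")
        frames.append(coords)
        i += 2 + n
        frame_no += 1
    if not frames:
        raise TrajectoryError(f"no frames in {path}")
    return names0, np.stack(frames)


def write_xyz(path, names: list[str], frames: np.ndarray, comment: str = "") -> None:
    frames = np.asarray(frames, dtype=float)
    with open(path, "w") as fh:
        for f, coords in enumerate(frames):
            fh.write(f"{len(names)}\n{comment} frame {f}\n")
            for name, (x, y, z) in zip(names, coords):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_multimodel_pdb(path) -> tuple[list[str], list[str], np.ndarray]:
    frames: list[list[list[float]]] = []
    names: list[str] = []
    resnames: list[str] = []
    current: list[list[float]] | None = None
    first = True
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = []
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                current.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
                if first:
                    names.append(line[12:16].strip())
                    resnames.append(line[17:20].strip())
            elif rec == "ENDMDL":
                if current:
                    if frames and len(current) != len(frames[0]):
                        raise TrajectoryError(
                            f"frame {len(frames)}: atom count {len(current)} != {len(frames[0])}"
                        )
                    frames.append(current)
                    first = False
                current = None
    if current:  # file without MODEL/ENDMDL bracketing
        if frames and len(current) != len(frames[0]):
            raise TrajectoryError(f"final frame atom count {len(current)} != {len(frames[0])}")
        frames.append(current)
    if not frames:
        raise TrajectoryError(f"no coordinate frames in {path}")
    return names, resnames, np.array(frames, dtype=float)


_STANDARD_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _groups_from_pdb(resnames: list[str], selections: dict[str, str]) -> dict[str, np.ndarray]:
    groups = {}
    for gname, sel in selections.items():
        if sel == "protein":
            idx = [i for i, rn in enumerate(resnames) if rn in _STANDARD_RESNAMES]
        else:
            idx = [i for i, rn in enumerate(resnames) if rn.upper() == sel.upper()]
        groups[gname] = np.asarray(idx, dtype=int)
    return groups


def _groups_from_names(names: list[str], selections: dict[str, str]) -> dict[str, np.ndarray]:
    claimed: set[int] = set()
    groups: dict[str, np.ndarray] = {}
    protein_keys = [g for g, s in selections.items() if s == "protein"]
    for gname, sel in selections.items():
        if sel == "protein":
            continue
        idx = [i for i, nm in enumerate(names) if nm.upper() == sel.upper()]
        claimed.update(idx)
        groups[gname] = np.asarray(idx, dtype=int)
    for gname in protein_keys:
        groups[gname] = np.asarray(
            [i for i in range(len(names)) if i not in claimed], dtype=int
        )
    return groups


# ---------------------------------------------------------------------------
# Distributions


def _min_distances(traj: Trajectory, ion_idx: np.ndarray, ref_idx: np.ndarray) -> np.ndarray:
    """(n_frames, n_ions) minimum ion-to-reference distances, no imaging."""
    from scipy.spatial import cKDTree

    out = np.empty((traj.n_frames, len(ion_idx)))
    for f in range(traj.n_frames):
        tree = cKDTree(traj.frames[f, ref_idx])
        d, _ = tree.query(traj.frames[f, ion_idx])
        out[f] = d
    return out


def _sampling_bounds(traj: Trajectory, pad: float) -> tuple[np.ndarray, np.ndarray]:
    coords = traj.frames.reshape(-1, 3)
    return coords.min(axis=0) - pad, coords.max(axis=0) + pad


def rdf_min_distance(
    traj: Trajectory,
    ions: str = "ions",
    protein: str = "protein",
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float = DEFAULT_R_MAX,
    reference: str = "mc_ideal",
    seed: int = 0,
    n_reference: int | None = None,
) -> RdfCurve:
    """Distribution of each ion's minimum distance to the protein surface.

    reference="mc_ideal": normalised by the identical statistic for
    pseudo-ions placed uniformly (seeded) in the trajectory's box (or the
    padded coordinate bounding box when no box is present); ≈1 everywhere
    means no preferential association. reference="raw": probability density
    over the same bins.
    """
    if r_max <= bin_width:
        raise ValueError(f"r_max ({r_max}) must exceed bin_width ({bin_width})")
    ion_idx, prot_idx = traj.group(ions), traj.group(protein)
    if len(ion_idx) == 0 or len(prot_idx) == 0:
        raise ValueError("ion and protein groups must be non-empty")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    dmin = _min_distances(traj, ion_idx, prot_idx).ravel()
    counts, _ = np.histogram(dmin, bins=edges)

    meta = {
        "mode": "min_distance_to_surface",
        "bin_width_A": bin_width,
        "r_max_A": r_max,
        "n_ions": int(len(ion_idx)),
        "note": "whole-surface association curve; not a pair g(r)",
    }
    if reference == "raw":
        total = counts.sum()
        g = counts / (total * bin_width) if total else np.zeros_like(counts, dtype=float)
        return RdfCurve(edges, g, "raw", traj.n_frames, meta)
    if reference != "mc_ideal":
        raise ValueError(f"unknown reference mode {reference!r}")

    rng = np.random.default_rng(seed)
    n_pseudo = n_reference or max(20 * len(ion_idx), 2000)
    if traj.box is not None:
        lo = np.zeros(3)
        hi = traj.box.mean(axis=0)
    else:
        lo, hi = _sampling_bounds(traj, pad=r_max / 2)
    from scipy.spatial import cKDTree

    ref_counts = np.zeros(len(edges) - 1)
    for f in range(traj.n_frames):
        pseudo = rng.uniform(lo, hi, size=(n_pseudo, 3))
        tree = cKDTree(traj.frames[f, prot_idx])
        d, _ = tree.query(pseudo)
        c, _ = np.histogram(d, bins=edges)
        ref_counts += c
    n_real = len(ion_idx) * traj.n_frames
    n_ref = n_pseudo * traj.n_frames
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (counts / n_real) / (ref_counts / n_ref)
    g = np.where(ref_counts > 0, g, 0.0)
    meta["n_reference_per_frame"] = n_pseudo
    meta["seed"] = seed
    return RdfCurve(edges, g, "mc_ideal", traj.n_frames, meta)


def rdf_site(
    traj: Trajectory,
    site: str,
    ions: str = "ions",
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float = DEFAULT_R_MAX,
) -> RdfCurve:
    """Standard site-ion pair g(r) under the minimum-image convention.

    Requires an orthorhombic box: counts per shell are normalised by the
    ideal-gas expectation (bulk ion density x shell volume x frames x
    site-atom count).
    """
    if traj.box is None:
        raise ValueError("site-mode g(r) requires a periodic box")
    if r_max <= bin_width:
        raise ValueError(f"r_max ({r_max}) must exceed bin_width ({bin_width})")
    site_idx, ion_idx = traj.group(site), traj.group(ions)
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts = np.zeros(len(edges) - 1)
    volume = 0.0
    for f in range(traj.n_frames):
        box = traj.box[f]
        volume += float(np.prod(box))
        delta = traj.frames[f, ion_idx][None, :, :] - traj.frames[f, site_idx][:, None, :]
        delta -= box * np.round(delta / box)  # minimum image
        d = np.linalg.norm(delta, axis=-1).ravel()
        c, _ = np.histogram(d, bins=edges)
        counts += c
    volume /= traj.n_frames
    rho = len(ion_idx) / volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = rho * shell * traj.n_frames * len(site_idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(norm > 0, counts / norm, 0.0)
    return RdfCurve(
        edges,
        g,
        "bulk_density",
        traj.n_frames,
        {"mode": "site_pair_gr", "bin_width_A": bin_width, "r_max_A": r_max},
    )


def find_peaks(
    curve: RdfCurve, min_height: float = 1.0, min_separation: float = 0.3
) -> list[float]:
    """Local maxima of g(r) above ``min_height``, at least ``min_separation`` Å apart."""
    bin_width = float(curve.bin_edges[1] - curve.bin_edges[0])
    distance = max(1, int(round(min_separation / bin_width)))
    idx, _ = _scipy_find_peaks(curve.g, height=min_height, distance=distance)
    return [float(r) for r in curve.bin_centers[idx]]


def residence_events(
    traj: Trajectory,
    ions: str = "ions",
    site: str = "protein",
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    site_label: str | None = None,
) -> list[ResidenceEvent]:
    """Gap-tolerant residence intervals of each ion at a site.

    A frame is a contact when the ion's minimum distance to any site atom is
    <= ``contact_cutoff``; contact runs separated by <= ``gap_tolerance``
    non-contact frames are merged into one event.
    """
    ion_idx = traj.group(ions)
    site_idx = traj.group(site)
    label = site_label or site
    dmin = _min_distances(traj, ion_idx, site_idx)
    events = []
    for i in range(len(ion_idx)):
        inside = dmin[:, i] <= contact_cutoff
        events.extend(
            ResidenceEvent(ion=int(ion_idx[i]), site=label, start_frame=s, end_frame=e)
            for s, e in merge_runs(inside, gap_tolerance)
        )
    return events


def merge_runs(inside: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Contiguous True runs, merging runs separated by <= gap_tolerance Falses."""
    runs = []
    start = None
    for f, flag in enumerate(inside):
        if flag and start is None:
            start = f
        elif not flag and start is not None:
            runs.append((start, f - 1))
            start = None
    if start is not None:
        runs.append((start, len(inside) - 1))
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= gap_tolerance:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def compare_association(
    curve_a: RdfCurve, curve_b: RdfCurve, r_window: tuple[float, float]
) -> float:
    """Ratio of integrated association (area under g) of A over B in a window."""
    if curve_a.bin_edges.shape != curve_b.bin_edges.shape or not np.allclose(
        curve_a.bin_edges, curve_b.bin_edges
    ):
        raise ValueError("curves have incompatible binning")
    lo, hi = r_window
    centers = curve_a.bin_centers
    mask = (centers >= lo) & (centers <= hi)
    if not mask.any():
        raise ValueError(f"window {r_window} selects no bins")
    area_b = float(np.trapezoid(curve_b.g[mask], centers[mask]))
    area_a = float(np.trapezoid(curve_a.g[mask], centers[mask]))
    if area_b == 0:
        raise ZeroDivisionError("reference curve has zero area in window")
    return area_a / area_b
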