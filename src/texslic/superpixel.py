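"""Texture-augmented SLIC with a gray-gated cluster-center update.

Standard SLIC is k-means in a joint feature+position space with the search
for each seed restricted to a 2S x 2S window, where ``S = sqrt(N/K)`` is
the seeding span.  Here the feature space is (gray, texture code) and the
combined distance for a pixel *i* against center *k* is

    D = sqrt( (d_c / Nc_k)^2 + (d_s / S)^2 + (d_t / Nt_k)^2 )

with ``d_c = |CO_k - g_i|`` the gray distance, ``d_s`` the Euclidean
position distance and ``d_t = |t_k - t_i|`` the texture-code distance.
``Nc_k`` and ``Nt_k`` are per-cluster adaptive normalizers: they start at
the configured compactness constants and are replaced each iteration by the
largest gray / texture distance observed within the cluster, so no global
compactness parameter needs tuning.

The center update is *gray-gated*: members whose gray differs from the
center's pre-update gray by at least ``alpha`` (the standard deviation of
the clustered image's gray values) are excluded from the mean, so outlier
pixels misassigned in early sweeps cannot drag centers off their tissue.
If the gate would empty a cluster, the plain mean over all members is used
instead; a cluster that loses all members is retired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage import measure

from ._util import validate_gray_image
from .config import PipelineConfig

__all__ = [
    "ClusterCenters",
    "LabelMap",
    "init_centers",
    "pixel_distance",
    "assign_pixels",
    "update_centers",
    "iterate",
    "enforce_connectivity",
    "boundary_mask",
]

logger = logging.getLogger("texslic")


@dataclass
class ClusterCenters:
    """Struct-of-arrays state of the K cluster centers.

    ``gray``/``row``/``col``/``tex`` are float64; ``nc``/``nt`` are the
    adaptive gray/texture normalizers (always >= 1); ``active`` marks
    centers that still own pixels.
    """

    gray: np.ndarray
    row: np.ndarray
    col: np.ndarray
    tex: np.ndarray
    nc: np.ndarray
    nt: np.ndarray
    active: np.ndarray

    def __len__(self) -> int:
        return self.gray.shape[0]


@dataclass
class LabelMap:
    """Per-pixel assignment state plus the run's global constants.

    ``labels`` holds the superpixel index per pixel (-1 before the first
    assignment), ``dists`` the best combined distance.  ``span`` is the
    seeding span S, ``alpha`` the gray-gate threshold, and ``audit`` an
    optional per-iteration record of gate behavior.
    """

    labels: np.ndarray
    dists: np.ndarray
    n_requested: int
    span: float
    n_pixels: int
    alpha: float
    audit: list[dict[str, Any]] = field(default_factory=list)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) + 1


def init_centers(
    image: np.ndarray,
    tex: np.ndarray | None,
    n_superpixels: int,
    compactness_gray: float = 10.0,
    compactness_texture: float = 10.0,
) -> tuple[ClusterCenters, LabelMap]:
    """Seed K centers on a regular grid with span ``S = sqrt(N/K)``.

    Each center samples its gray (and texture code, when a texture map is
    supplied) at its grid point.  The returned label map is unassigned
    (labels -1, distances inf) and carries ``alpha``, the population
    standard deviation of the image's gray values, as the gate threshold.
    """
    img = validate_gray_image(image)
    h, w = img.shape
    n = h * w
    if n_superpixels < 1:
        raise ValueError("n_superpixels must be >= 1")
    if n_superpixels > n:
        raise ValueError(f"n_superpixels={n_superpixels} exceeds pixel count {n}")
    span = float(np.sqrt(n / n_superpixels))
    n_rows = max(1, round(h / span))
    n_cols = max(1, round(w / span))
    rows = (np.arange(n_rows) + 0.5) * (h / n_rows)
    cols = (np.arange(n_cols) + 0.5) * (w / n_cols)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    rr = rr.ravel()
    cc = cc.ravel()
    ri = np.clip(np.floor(rr).astype(int), 0, h - 1)
    ci = np.clip(np.floor(cc).astype(int), 0, w - 1)
    k = rr.size
    tex_vals = (
        tex[ri, ci].astype(np.float64) if tex is not None else np.zeros(k)
    )
    centers = ClusterCenters(
        gray=img[ri, ci].astype(np.float64),
        row=rr.astype(np.float64),
        col=cc.astype(np.float64),
        tex=tex_vals,
        nc=np.full(k, float(compactness_gray)),
        nt=np.full(k, float(compactness_texture)),
        active=np.ones(k, dtype=bool),
    )
    state = LabelMap(
        labels=np.full((h, w), -1, dtype=np.int32),
        dists=np.full((h, w), np.inf),
        n_requested=n_superpixels,
        span=span,
        n_pixels=n,
        alpha=float(img.std()),
    )
    return centers, state


def pixel_distance(
    center_gray: float,
    center_pos: tuple[float, float],
    center_tex: float,
    gray: np.ndarray | float,
    row: np.ndarray | float,
    col: np.ndarray | float,
    tex: np.ndarray | float | None,
    span: float,
    nc: float,
    nt: float,
    literal: bool = False,
) -> np.ndarray:
    """Combined gray+space(+texture) distance of pixels to one center.

    ``gray``/``row``/``col``/``tex`` may be scalars or arrays.  When
    ``tex`` is None the texture term is omitted.  ``literal=True`` squares
    the gray and texture differences before normalization, the comparison
    mode in which those components enter the norm at fourth power.
    """
    d_c = np.abs(np.asarray(gray, dtype=np.float64) - center_gray)
    d_s = np.sqrt(
        (np.asarray(row, dtype=np.float64) - center_pos[0]) ** 2
        + (np.asarray(col, dtype=np.float64) - center_pos[1]) ** 2
    )
    if literal:
        d_c = d_c**2
    total = (d_c / nc) ** 2 + (d_s / span) ** 2
    if tex is not None:
        d_t = np.abs(np.asarray(tex, dtype=np.float64) - center_tex)
        if literal:
            d_t = d_t**2
        total = total + (d_t / nt) ** 2
    return np.sqrt(total)


def assign_pixels(
    centers: ClusterCenters,
    image: np.ndarray,
    tex: np.ndarray | None,
    state: LabelMap,
    literal: bool = False,
) -> LabelMap:
    """One assignment sweep: each center claims pixels in its 2S x 2S window.

    Best distances persist across sweeps (they are initialized to inf only
    at seeding), so a pixel's label can only improve; ties keep the earlier
    (lower-index) center.  Raises ``RuntimeError`` if any pixel remains
    uncovered after the sweep — the initial seed windows tile the image,
    so this indicates an internal defect.
    """
    img = image.astype(np.float64)
    h, w = img.shape
    s = state.span
    for k in range(len(centers)):
        if not centers.active[k]:
            continue
        r, c = centers.row[k], centers.col[k]
        r0 = max(0, int(np.ceil(r - s)))
        r1 = min(h, int(np.floor(r + s)) + 1)
        c0 = max(0, int(np.ceil(c - s)))
        c1 = min(w, int(np.floor(c + s)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rows, cols = np.meshgrid(
            np.arange(r0, r1), np.arange(c0, c1), indexing="ij"
        )
        d = pixel_distance(
            centers.gray[k],
            (r, c),
            centers.tex[k],
            img[r0:r1, c0:c1],
            rows,
            cols,
            tex[r0:r1, c0:c1] if tex is not None else None,
            s,
            centers.nc[k],
            centers.nt[k],
            literal=literal,
        )
        window_d = state.dists[r0:r1, c0:c1]
        better = d < window_d
        window_d[better] = d[better]
        state.labels[r0:r1, c0:c1][better] = k
    if np.any(state.labels < 0):
        n_missed = int(np.count_nonzero(state.labels < 0))
        raise RuntimeError(
            f"{n_missed} pixels fell outside every search window; "
            "seed windows no longer tile the image"
        )
    return state


def update_centers(
    centers: ClusterCenters,
    image: np.ndarray,
    tex: np.ndarray | None,
    state: LabelMap,
    gated: bool = True,
    record_audit: bool = False,
) -> ClusterCenters:
    """Recompute each center from its members; optionally gray-gated.

    With ``gated=True``, only members whose gray differs from the center's
    pre-update gray by less than ``alpha`` enter the gray/position/texture
    means; an empty gate falls back to all members.  The adaptive
    normalizers are set to the largest gray / texture distance seen among
    *all* members this iteration (floor 1).  ``alpha == 0`` (constant
    image) disables the gate.  Centers with no members are retired.
    """
    img = image.astype(np.float64).ravel()
    h, w = state.labels.shape
    labels = state.labels.ravel()
    rows = (np.arange(h * w) // w).astype(np.float64)
    cols = (np.arange(h * w) % w).astype(np.float64)
    texv = tex.astype(np.float64).ravel() if tex is not None else None
    alpha = state.alpha
    use_gate = gated and alpha > 0

    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    boundaries = np.searchsorted(sorted_labels, np.arange(len(centers) + 1))
    audit_entry: dict[str, Any] = {"fallbacks": [], "max_gated_diff": 0.0, "gated": use_gate}

    for k in range(len(centers)):
        members = order[boundaries[k] : boundaries[k + 1]]
        if members.size == 0:
            centers.active[k] = False
            continue
        d_c = np.abs(img[members] - centers.gray[k])
        centers.nc[k] = max(float(d_c.max()), 1.0)
        if texv is not None:
            d_t = np.abs(texv[members] - centers.tex[k])
            centers.nt[k] = max(float(d_t.max()), 1.0)
        if use_gate:
            inside = d_c < alpha
            if inside.any():
                chosen = members[inside]
                if record_audit:
                    audit_entry["max_gated_diff"] = max(
                        audit_entry["max_gated_diff"], float(d_c[inside].max())
                    )
            else:
                chosen = members
                if record_audit:
                    audit_entry["fallbacks"].append(k)
        else:
            chosen = members
        centers.gray[k] = img[chosen].mean()
        centers.row[k] = rows[chosen].mean()
        centers.col[k] = cols[chosen].mean()
        if texv is not None:
            centers.tex[k] = texv[chosen].mean()
    if record_audit:
        state.audit.append(audit_entry)
    return centers


def iterate(
    image: np.ndarray,
    tex: np.ndarray | None,
    cfg: PipelineConfig,
    record_audit: bool = False,
) -> tuple[LabelMap, ClusterCenters]:
    """Run the full assignment/update loop for ``cfg.n_iterations`` sweeps.

    Deterministic for fixed inputs.  Logs the mean center displacement per
    iteration at INFO level.  Returns the final label map (labels are from
    the last assignment sweep) and the converged centers.
    """
    img = validate_gray_image(image)
    centers, state = init_centers(
        img,
        tex,
        cfg.n_superpixels,
        cfg.compactness_gray,
        cfg.compactness_texture,
    )
    for it in range(cfg.n_iterations):
        assign_pixels(centers, img, tex, state, literal=cfg.literal_distances)
        prev_r = centers.row.copy()
        prev_c = centers.col.copy()
        update_centers(
            centers, img, tex, state, gated=cfg.use_gated_update,
            record_audit=record_audit,
        )
        act = centers.active
        if act.any():
            disp = np.hypot(
                centers.row[act] - prev_r[act], centers.col[act] - prev_c[act]
            ).mean()
        else:
            disp = 0.0
        logger.info("iteration %d: mean center displacement %.3f px", it + 1, disp)
    return state, centers


def enforce_connectivity(
    state: LabelMap, image: np.ndarray | None = None
) -> LabelMap:
    """Merge stray fragments so every superpixel is one 4-connected blob.

    Connected components (4-connectivity) of the label image smaller than
    ``S^2 / 4`` pixels are merged, smallest first, into a 4-adjacent
    neighboring component.  When ``image`` (the raster that was clustered)
    is given, the target is the neighbor with the closest mean gray, so an
    orphan sliver of tissue is reunited with tissue rather than swallowed
    by a large background superpixel; ties — and the no-image case — go to
    the largest neighbor.  Labels are then re-densified to ``0..K'-1``.
    """
    labels = state.labels
    if labels.min() < 0:
        raise ValueError("label map has unassigned pixels")
    # background=-1: label 0 is a real superpixel, not background
    comp = measure.label(labels, connectivity=1, background=-1)
    n_comp = int(comp.max())
    sizes = np.bincount(comp.ravel(), minlength=n_comp + 1).astype(np.int64)
    if image is not None:
        img = np.asarray(image, dtype=np.float64).ravel()
        gray_sum = np.bincount(comp.ravel(), weights=img, minlength=n_comp + 1)
    else:
        gray_sum = None

    # component adjacency from horizontal and vertical label changes
    adj: list[set[int]] = [set() for _ in range(n_comp + 1)]
    for a, b in (
        (comp[:, :-1], comp[:, 1:]),
        (comp[:-1, :], comp[1:, :]),
    ):
        diff = a != b
        for x, y in zip(a[diff].ravel(), b[diff].ravel()):
            adj[x].add(int(y))
            adj[y].add(int(x))

    parent = np.arange(n_comp + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    min_size = max(1, int(state.span**2 / 4))
    for c in sorted(range(1, n_comp + 1), key=lambda c: (sizes[c], c)):
        root = find(c)
        if sizes[root] >= min_size:
            continue
        neighbor_roots = {find(n) for n in adj[c]} - {root}
        if not neighbor_roots:
            continue
        if gray_sum is not None:
            own_mean = gray_sum[root] / sizes[root]
            target = min(
                neighbor_roots,
                key=lambda r: (
                    abs(gray_sum[r] / sizes[r] - own_mean),
                    -sizes[r],
                    r,
                ),
            )
        else:
            target = max(neighbor_roots, key=lambda r: (sizes[r], -r))
        parent[root] = target
        sizes[target] += sizes[root]
        if gray_sum is not None:
            gray_sum[target] += gray_sum[root]

    roots = np.array([find(c) for c in range(n_comp + 1)])
    final = roots[comp]
    _, dense = np.unique(final, return_inverse=True)
    state.labels = dense.reshape(labels.shape).astype(np.int32)
    state.span = float(state.span)
    return state


def boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels with at least one 4-neighbor of another label.

    Image border pixels are not boundary merely for touching the border.
    """
    lab = np.asarray(labels)
    if lab.ndim != 2:
        raise ValueError("labels must be 2-D")
    mask = np.zeros(lab.shape, dtype=bool)
    horiz = lab[:, :-1] != lab[:, 1:]
    mask[:, :-1] |= horiz
    mask[:, 1:] |= horiz
    vert = lab[:-1, :] != lab[1:, :]
    mask[:-1, :] |= vert
    mask[1:, :] |= vert
    return mask
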