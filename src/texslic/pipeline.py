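"""Stage wiring: raw image in, superpixel label map out.

The four variants form an ablation ladder:

``slic``
    plain SLIC on the raw image (gray + position distance, plain update);
``enforced_slic``
    3-D histogram reconstruction and gamma enhancement first, then plain
    SLIC;
``improved_slic``
    preprocessing plus the gray-gated center update, no texture term;
``proposed``
    the full pipeline: preprocessing, LTriDP magnitude texture in the
    distance, and the gated update.
"""

from __future__ import annotations

import logging
import time

import numpy as np

from ._util import validate_gray_image
from .config import PipelineConfig
from .enhance import gamma_enhance
from .reconstruct import reconstruct_image
from .superpixel import LabelMap, enforce_connectivity, iterate
from .texture import texture_map

__all__ = ["run_pipeline"]

logger = logging.getLogger("texslic")


def run_pipeline(
    image: np.ndarray,
    cfg: PipelineConfig | None = None,
    record_audit: bool = False,
) -> LabelMap:
    """Segment an 8-bit gray image into superpixels.

    Deterministic for a fixed image and config.  The returned
    :class:`LabelMap` carries the executed stage names in ``.stages``.
    """
    cfg = cfg or PipelineConfig()
    img = validate_gray_image(image)
    stages: list[str] = []

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        out = fn(*args)
        stages.append(name)
        logger.info("stage %-12s %6.1f ms", name, 1e3 * (time.perf_counter() - t0))
        return out

    work = img
    if cfg.use_preprocessing:
        work = timed("reconstruct", reconstruct_image, work, cfg.theta)
        work = timed("enhance", gamma_enhance, work, cfg.gamma)
    tex = timed("texture", texture_map, work) if cfg.use_texture else None
    state, _centers = timed(
        "cluster", iterate, work, tex, cfg, record_audit
    )
    if cfg.enforce_connectivity:
        state = timed("connectivity", enforce_connectivity, state, work)
    state.stages = stages  # type: ignore[attr-defined]
    return state
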