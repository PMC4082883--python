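"""End-to-end assembly: image -> cost graph -> contour -> mask.

Two interchangeable edge features feed the same combined link cost:

* ``classic``  — Laplacian-of-Gaussian zero crossings (the traditional
  Live Wire edge term);
* ``gaborfcm`` — boundaries of fuzzy-c-means texture clusters computed from a
  Gabor filter bank, which stay put where gradient-based features drown in
  noise or smear across a lesion's fuzzy halo.
"""

from __future__ import annotations

import numpy as np

from . import classic_cost, gabor_fcm, livewire
from .config import LumpwireConfig
from .image_core import IntensityImage, ValidationError, gaussian_smooth, gradients

COST_METHODS = ("classic", "gaborfcm")


def build_cost_graph(img: IntensityImage, method: str = "classic",
                     config: LumpwireConfig | None = None
                     ) -> livewire.LinkCostGraph:
    """Link-cost graph for one image under the chosen edge feature."""
    if method not in COST_METHODS:
        raise ValidationError(f"unknown cost method {method!r}")
    cfg = config or LumpwireConfig()
    work = img
    if cfg.presmooth_sigma:
        work = gaussian_smooth(img, cfg.presmooth_sigma)
    grad = gradients(work)
    f_g = classic_cost.gradient_magnitude_cost(grad)
    if method == "classic":
        edge = classic_cost.laplacian_zero_crossing(work, cfg.log_sigma)
    else:
        gf = cfg.gabor_fcm
        edge = gabor_fcm.gabor_fcm_edge_map(
            work,
            c=gf.c, m=gf.m, eps=gf.eps, max_iter=gf.max_iter, seed=gf.seed,
            gamma=gf.gamma, phi=gf.phi, sigma_rule=gf.sigma_rule,
            smoothing_factor=gf.smoothing_factor,
            orientations=tuple(gf.orientations),
        )
    weights = classic_cost.CostWeights(cfg.w_z, cfg.w_g, cfg.w_d)
    return classic_cost.combine_costs(edge, f_g, grad, weights)


def segment_image(img: IntensityImage, clicks: list[tuple[int, int]],
                  method: str = "classic",
                  config: LumpwireConfig | None = None) -> np.ndarray:
    """Segment one image from ordered boundary clicks; returns a binary mask."""
    graph = build_cost_graph(img, method=method, config=config)
    contour = livewire.segment_with_clicks(graph, clicks)
    return livewire.contour_to_mask(contour, img.shape)
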