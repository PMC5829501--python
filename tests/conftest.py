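"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use plain Python loops (no vectorisation, no calls
into the package) so they stay independent of the implementations they
check: annulus statistics, seed-connected flood fill and thresholded mass
summation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


def oracle_annulus_stats(frame, center, r_in, r_out, ddof=0):
    """Mean/stdev/count over inner < d <= outer by exhaustive pixel loop."""
    vals = []
    cy, cx = center
    for y in range(len(frame)):
        for x in range(len(frame[0])):
            d2 = (y - cy) ** 2 + (x - cx) ** 2
            if r_in**2 < d2 <= r_out**2:
                vals.append(float(frame[y][x]))
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / (n - ddof)
    return mean, math.sqrt(var), n


def oracle_flood_fill(frame, threshold, seed):
    """Set of pixels in the seed's 8-connected suprathreshold component."""
    ny, nx = len(frame), len(frame[0])
    sy, sx = seed
    if not frame[sy][sx] > threshold:
        return set()
    visited = {(sy, sx)}
    stack = [(sy, sx)]
    while stack:
        y, x = stack.pop()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                yy, xx = y + dy, x + dx
                if (
                    0 <= yy < ny
                    and 0 <= xx < nx
                    and (yy, xx) not in visited
                    and frame[yy][xx] > threshold
                ):
                    visited.add((yy, xx))
                    stack.append((yy, xx))
    return visited


def oracle_mass(frame, roi_pixels, threshold):
    """Sum of (pixel - threshold) over an explicit pixel set."""
    return sum(float(frame[y][x]) - threshold for (y, x) in roi_pixels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def spot_frame():
    """Deterministic frame: Gaussian spot of known total mass on background."""

    def make(mass=50_000.0, center=(24.0, 24.0), background=500.0, shape=(48, 48), sigma=2.0):
        yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
        spot = (mass / (2 * np.pi * sigma**2)) * np.exp(
            -(((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2))
        )
        return background + spot

    return make
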