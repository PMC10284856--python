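"""Shared fixtures: toy geometries and an independent Gauss-integral oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from foldtrap.synthetic import ToyLinkSpec, gen_entangled_toy
from foldtrap.topology import CalphaStructure


def dense_gauss_oracle(curve_a, curve_b, subdivisions: int = 40) -> float:
    """Independent dense-quadrature Gauss linking integral.

    Each polygonal segment is subdivided into many short pieces and the
    double integral evaluated with a plain midpoint rule in a scalar
    loop.  Converges to the exact Gauss integral of the polygonal pair;
    deliberately written without reusing the production vectorized code.
    """
    def refine(curve):
        pts = []
        for p, q in zip(curve[:-1], curve[1:]):
            for k in range(subdivisions):
                pts.append(p + (q - p) * k / subdivisions)
        pts.append(curve[-1])
        return np.asarray(pts, dtype=float)

    a, b = refine(np.asarray(curve_a)), refine(np.asarray(curve_b))
    total = 0.0
    for i in range(len(a) - 1):
        ra = (a[i] + a[i + 1]) / 2.0
        da = a[i + 1] - a[i]
        for j in range(len(b) - 1):
            rb = (b[j] + b[j + 1]) / 2.0
            db = b[j + 1] - b[j]
            r = ra - rb
            d = math.sqrt(r[0] ** 2 + r[1] ** 2 + r[2] ** 2)
            c = np.cross(da, db)
            total += float(np.dot(r, c)) / d ** 3
    return total / (4.0 * math.pi)


@pytest.fixture(scope="session")
def toy_pair():
    return gen_entangled_toy(ToyLinkSpec(handedness=+1))


def two_loop_chain(threaded: bool):
    """Chain with two well-separated bead circles and one thread.

    With 12 beads on a 12 Å circle only the closure pair (first/last
    bead) is a native contact: one-step chords are 6.2 Å but too close in
    sequence, two-step chords exceed the 8 Å cutoff.  The thread pierces
    loop A when ``threaded`` (the misfolded state) and is displaced far
    outside both loops otherwise; loop B is never threaded, so exactly
    one of the two closure contacts changes its linking state.
    """
    r, n = 12.0, 12
    ang = 2.0 * math.pi * np.arange(n) / n

    def circle(center):
        return np.column_stack([center[0] + r * np.cos(ang),
                                center[1] + r * np.sin(ang),
                                np.full(n, center[2])])

    loop_a = circle((0.0, 0.0, 0.0))
    loop_b = circle((120.0, 0.0, 0.0))

    def bridge(p, q, k=6, z_clamp=None):
        frac = np.linspace(0.0, 1.0, k + 2)[1:-1]
        pts = p[None, :] + frac[:, None] * (q - p)[None, :]
        if z_clamp is not None:
            pts[:, 2] = np.minimum(pts[:, 2], z_clamp)
        return pts

    y_thread = 0.0 if threaded else 60.0
    thread = np.column_stack([np.zeros(16), np.full(16, y_thread),
                              np.linspace(-30.0, 30.0, 16)])
    chain = np.vstack([
        loop_a,
        bridge(loop_a[-1], loop_b[0], z_clamp=-12.0),
        loop_b,
        bridge(loop_b[-1], thread[0], z_clamp=-15.0),
        thread,
    ])
    return CalphaStructure(coords=chain, synthetic=True)


@pytest.fixture(scope="session")
def two_loop_native():
    return two_loop_chain(threaded=False)


@pytest.fixture(scope="session")
def two_loop_misfolded():
    return two_loop_chain(threaded=True)
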