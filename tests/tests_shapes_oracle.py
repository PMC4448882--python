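"""Independent point-scatterer oracle for the shape form factors.

Averages exp(i q·r) over points uniformly distributed on each shape:
10⁴ midpoint samples on the ring and the line segment, and a
Gauss-Legendre × uniform-azimuth product grid on the sphere.
"""

import math

import numpy as np


def _perp_basis(axis):
    seed = np.array([1.0, 0.0, 0.0])
    if abs(axis @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ axis) * axis
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


def brute_force_average(kind, magnitude, axis, q, n=10_000):
    if kind == "torus":
        phi = 2 * math.pi * (np.arange(n) + 0.5) / n
        e1, e2 = _perp_basis(axis)
        pts = magnitude * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2))
    elif kind == "line":
        t = magnitude * ((np.arange(n) + 0.5) / n - 0.5)
        pts = np.outer(t, axis)
    elif kind == "shell":
        ng = 100
        x, w = np.polynomial.legendre.leggauss(ng)
        phi = 2 * math.pi * (np.arange(ng) + 0.5) / ng
        ct, ph = np.meshgrid(x, phi)
        st = np.sqrt(1 - ct**2)
        pts = magnitude * np.stack([st * np.cos(ph), st * np.sin(ph), ct], axis=-1).reshape(-1, 3)
        wts = np.tile(w, ng)
        vals = np.exp(1j * pts @ q)
        return float(np.real(np.sum(wts * vals) / np.sum(wts)))
    else:
        raise ValueError(kind)
    return float(np.real(np.exp(1j * pts @ q).mean()))
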