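"""Numerical 1-D scattering through the Eckart potential (Numerov method).

Independent oracle for the closed-form transmission in
:mod:`stabkin.eckart_tunneling`: the potential is built directly from the
forward/reverse barriers, the length scale is fixed numerically from the
imaginary frequency (curvature at the top), and the time-independent
Schroedinger equation is integrated with outgoing-wave boundary
conditions.  Shares no algebra with the closed form beyond the potential
definition itself.
"""
from __future__ import annotations

import math

import numpy as np

from . import constants as const
from .eckart_tunneling import EckartBarrier


def _eckart_potential(x: np.ndarray, a: float, b: float, length: float) -> np.ndarray:
    """V(x) with asymptotes V(-inf)=0, V(+inf)=a and max (a+b)^2/(4b)."""
    y = -np.exp(2.0 * np.pi * x / length)
    return -a * y / (1.0 - y) - b * y / (1.0 - y) ** 2


def _length_for_curvature(a: float, b: float, omega: float) -> float:
    """Length L such that sqrt(|V''(x_max)|/mu) = omega with mu = 1.

    V'' scales as 1/L^2, so one numerical curvature evaluation at L = 1
    fixes L.  Avoids transcribing the analytic curvature relation (which
    is exactly what the oracle must not share with the closed form).
    """
    # position of the maximum for L=1: y_max = -(a+b)/(b-a) if b>a else from d/dx
    h = 1e-4
    # find max numerically on a coarse grid then refine
    xs = np.linspace(-6, 6, 4001)
    v = _eckart_potential(xs, a, b, 1.0)
    x0 = xs[np.argmax(v)]
    for _ in range(60):
        d1 = (_eckart_potential(np.array([x0 + h]), a, b, 1.0)[0]
              - _eckart_potential(np.array([x0 - h]), a, b, 1.0)[0]) / (2 * h)
        d2 = (_eckart_potential(np.array([x0 + h]), a, b, 1.0)[0]
              - 2 * _eckart_potential(np.array([x0]), a, b, 1.0)[0]
              + _eckart_potential(np.array([x0 - h]), a, b, 1.0)[0]) / h**2
        step = d1 / d2
        x0 -= step
        if abs(step) < 1e-12:
            break
    curv1 = abs(d2)  # |V''| at L=1
    return math.sqrt(curv1) / omega


def numerical_transmission(barrier: EckartBarrier, E: float,
                           n_points: int = 6001, span: float = 10.0) -> float:
    """Transmission at total energy E (kcal/mol from the reactant ZPE).

    Works in units hbar = mu = 1 with energies carried in cm^-1; the
    transmission depends only on E/V1, V2/V1 and V1/nu*, so the unit
    choice is immaterial.
    """
    v1 = barrier.v1_cm
    v2 = barrier.v2_cm
    e = E * const.KCAL_TO_CM
    a = v1 - v2
    b = (math.sqrt(v1) + math.sqrt(v2)) ** 2
    if e <= max(0.0, a):
        return 0.0
    length = _length_for_curvature(a, b, barrier.nu_imag)

    x = np.linspace(-span * length, span * length, n_points)
    h = x[1] - x[0]
    v = _eckart_potential(x, a, b, length)
    k1 = math.sqrt(2.0 * e)             # reactant side, V -> 0
    k2 = math.sqrt(2.0 * (e - a))       # product side, V -> a
    f = 2.0 * (e - v)                   # psi'' = -f psi

    # Numerov, integrating right -> left with transmitted wave exp(i k2 x)
    psi = np.zeros(n_points, dtype=complex)
    psi[-1] = np.exp(1j * k2 * x[-1])
    psi[-2] = np.exp(1j * k2 * x[-2])
    c = h * h / 12.0
    for i in range(n_points - 2, 0, -1):
        psi[i - 1] = ((2.0 * (1.0 - 5.0 * c * f[i]) * psi[i]
                       - (1.0 + c * f[i + 1]) * psi[i + 1])
                      / (1.0 + c * f[i - 1]))

    # decompose psi = A exp(i k1 x) + B exp(-i k1 x) on the reactant side
    x0, x1 = x[0], x[1]
    p0, p1 = psi[0], psi[1]
    det = (np.exp(1j * k1 * x0) * np.exp(-1j * k1 * x1)
           - np.exp(1j * k1 * x1) * np.exp(-1j * k1 * x0))
    A = (p0 * np.exp(-1j * k1 * x1) - p1 * np.exp(-1j * k1 * x0)) / det
    t = (k2 / k1) / abs(A) ** 2
    return float(min(max(t, 0.0), 1.0))
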