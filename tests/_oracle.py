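"""Independent dense density-matrix propagator for cross-checking spinsim.

Everything here is built from 4x4 complex matrices and scipy.linalg.expm;
no rotation rule, evolution rule or basis bookkeeping is shared with the
package's product-operator engine.  States are converted to/from the
16-coefficient Cartesian product-operator expansion only at the interface.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

_E2 = np.eye(2, dtype=complex)
_SX = 0.5 * np.array([[0, 1], [1, 0]], dtype=complex)
_SY = 0.5 * np.array([[0, -1j], [1j, 0]], dtype=complex)
_SZ = 0.5 * np.array([[1, 0], [0, -1]], dtype=complex)

IX = np.kron(_SX, _E2)
IY = np.kron(_SY, _E2)
IZ = np.kron(_SZ, _E2)
SX = np.kron(_E2, _SX)
SY = np.kron(_E2, _SY)
SZ = np.kron(_E2, _SZ)

_SINGLE = {"e": _E2, "x": _SX, "y": _SY, "z": _SZ}

# canonical basis order matching etherdnp.spinsim.BASIS_LABELS
_LABEL_PAIRS = [
    ("e", "e"),
    ("x", "e"), ("y", "e"), ("z", "e"),
    ("e", "x"), ("e", "y"), ("e", "z"),
    ("x", "x"), ("x", "y"), ("x", "z"),
    ("y", "x"), ("y", "y"), ("y", "z"),
    ("z", "x"), ("z", "y"), ("z", "z"),
]


def _basis_op(a: str, b: str) -> np.ndarray:
    op = np.kron(_SINGLE[a], _SINGLE[b])
    n_nonid = (a != "e") + (b != "e")
    return op * (2.0 ** (n_nonid - 1))


BASIS = [_basis_op(a, b) for a, b in _LABEL_PAIRS]


def rho_from_coeffs(coeffs: np.ndarray) -> np.ndarray:
    """Density operator from the 16 canonical-ordered real coefficients."""
    return sum(c * B for c, B in zip(coeffs, BASIS))


def coeffs_from_rho(rho: np.ndarray) -> np.ndarray:
    """Project a density operator onto the orthonormal product basis."""
    return np.array([np.trace(B.conj().T @ rho).real for B in BASIS])


def pulse_propagator(target: str, flip_deg: float, phase_deg: float) -> np.ndarray:
    """U = exp(-i * theta * (cos(phi) Fx + sin(phi) Fy)) for the target spin(s)."""
    theta = np.radians(flip_deg)
    phi = np.radians(phase_deg)
    if target == "I":
        gen = np.cos(phi) * IX + np.sin(phi) * IY
    elif target == "S":
        gen = np.cos(phi) * SX + np.sin(phi) * SY
    else:
        gen = np.cos(phi) * (IX + SX) + np.sin(phi) * (IY + SY)
    return expm(-1j * theta * gen)


def delay_propagator(J: float, offset_I: float, offset_S: float, t: float,
                     refocus_offsets: bool = False) -> np.ndarray:
    H = 2.0 * np.pi * J * (IZ @ SZ)
    if not refocus_offsets:
        H = H + 2.0 * np.pi * offset_I * IZ + 2.0 * np.pi * offset_S * SZ
    return expm(-1j * H * t)


def apply_unitary(rho: np.ndarray, U: np.ndarray) -> np.ndarray:
    return U @ rho @ U.conj().T


def apply_damping(rho: np.ndarray, t: float, T2I: float, T2S: float) -> np.ndarray:
    """T2' decay: diagonal in the product basis (transverse labels decay)."""
    fI = np.exp(-t / T2I) if np.isfinite(T2I) else 1.0
    fS = np.exp(-t / T2S) if np.isfinite(T2S) else 1.0
    coeffs = coeffs_from_rho(rho)
    out = coeffs.copy()
    for i, (a, b) in enumerate(_LABEL_PAIRS):
        if a in ("x", "y"):
            out[i] *= fI
        if b in ("x", "y"):
            out[i] *= fS
    return rho_from_coeffs(out)


def apply_zfilter(rho: np.ndarray, keep_zz: bool = False) -> np.ndarray:
    coeffs = coeffs_from_rho(rho)
    keep = {0, _LABEL_PAIRS.index(("z", "e")), _LABEL_PAIRS.index(("e", "z"))}
    if keep_zz:
        keep.add(_LABEL_PAIRS.index(("z", "z")))
    out = np.array([c if i in keep else 0.0 for i, c in enumerate(coeffs)])
    return rho_from_coeffs(out)


def detect(rho: np.ndarray, spin: str) -> complex:
    if spin == "I":
        return complex(np.trace(IX @ rho).real + 1j * np.trace(IY @ rho).real)
    return complex(np.trace(SX @ rho).real + 1j * np.trace(SY @ rho).real)


def run_transfer_experiment(J, tau, variant="perfect_echo",
                            offset_I=0.0, offset_S=0.0,
                            T2I=np.inf, T2S=np.inf,
                            flipdown_phases=None, receiver_phases=None,
                            flip_attenuation=1.0, flip_leakage=0.0,
                            amp_I=1.0, amp_S=1.0, zfilter_keep_zz=False):
    """Dense-matrix re-implementation of the full cycled experiment."""
    if flipdown_phases is None:
        if variant == "dq_filter":
            flipdown_phases = [90.0 * (k % 4) for k in range(8)]
            receiver_phases = [(270.0 - 2.0 * p) % 360.0 for p in flipdown_phases]
        else:
            flipdown_phases = [0, 0, 0, 0, 180, 180, 180, 180]
            receiver_phases = [270, 270, 270, 270, 90, 90, 90, 90]

    def sel_pulse(rho, phase):
        U = pulse_propagator("I", 90.0 * flip_attenuation, phase)
        rho = apply_unitary(rho, U)
        if flip_leakage:
            rho = apply_unitary(rho, pulse_propagator("S", 90.0 * flip_leakage, phase))
        return rho

    def half_delay(rho):
        rho = apply_unitary(rho, delay_propagator(J, offset_I, offset_S, tau))
        return apply_damping(rho, tau, T2I, T2S)

    sig_I, sig_S = [], []
    for k, phi in enumerate(flipdown_phases):
        shift = phi if variant == "dq_filter" else 0.0
        rho = amp_I * IX + amp_S * SX
        rho = sel_pulse(rho, 270.0)
        rho = apply_zfilter(rho, zfilter_keep_zz)
        rho = sel_pulse(rho, phi)
        rho = half_delay(rho)
        rho = apply_unitary(rho, pulse_propagator("both", 180.0, 0.0 + shift))
        rho = half_delay(rho)
        if variant == "perfect_echo":
            rho = apply_unitary(rho, pulse_propagator("both", 90.0, 270.0))
        elif variant == "dq_filter":
            rho = apply_unitary(rho, pulse_propagator("both", 90.0, 0.0 + shift))
            rho = apply_unitary(rho, pulse_propagator("both", 90.0, 0.0))
        rho = half_delay(rho)
        rho = apply_unitary(rho, pulse_propagator("both", 180.0, 0.0))
        rho = half_delay(rho)
        sig_I.append(detect(rho, "I"))
        sig_S.append(detect(rho, "S"))

    w = np.exp(-1j * np.radians(np.asarray(receiver_phases, dtype=float)))
    return (np.asarray(sig_I), np.asarray(sig_S),
            complex(np.mean(np.asarray(sig_I) * w)),
            complex(np.mean(np.asarray(sig_S) * w)))
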