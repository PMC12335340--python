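"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the production code paths: the spin-echo oracle
propagates the density matrix with matrix exponentials applied step by step
(1 us pieces through the echo train, one dwell per acquired point), instead
of the eigenbasis transition-amplitude evaluation used in production.
"""

import numpy as np
from scipy.linalg import expm

from mrsiglx.spin_sim import (
    AcquisitionParams,
    SequenceTiming,
    SpinSystem,
    _spin_operators,
    _subsystem_hamiltonian,
)


def brute_force_fid(
    system: SpinSystem,
    timing: SequenceTiming,
    acq: AcquisitionParams,
    step_s: float = 1e-6,
    n_points: int | None = None,
) -> np.ndarray:
    """Piecewise-constant-propagator simulation of the sLASER echo FID."""
    n_points = n_points or acq.n_points
    shifts = np.asarray(system.shifts)
    offsets = (shifts - acq.ref_ppm) * acq.larmor_freq
    jmat = system.j_matrix
    total = np.zeros(n_points, dtype=complex)
    for idx in system.subsystem_indices():
        total += _brute_force_block(
            offsets[idx], jmat[np.ix_(idx, idx)], timing, acq, step_s, n_points
        )
    return total


def _brute_force_block(offsets, jmat, timing, acq, step_s, n_points):
    n = len(offsets)
    ix, iy, iz = _spin_operators(n)
    h = _subsystem_hamiltonian(offsets, jmat, ix, iy, iz)
    rho = np.sum(ix, axis=0)
    fplus = rho + 1j * np.sum(iy, axis=0)
    r180 = expm(-1j * np.pi * np.sum(ix, axis=0))

    u_step = expm(-1j * h * step_s)
    for k, d_ms in enumerate(timing.delays):
        tau = d_ms * 1e-3
        n_full, rem = int(tau // step_s), tau - int(tau // step_s) * step_s
        for _ in range(n_full):
            rho = u_step @ rho @ u_step.conj().T
        if rem > 0:
            u_rem = expm(-1j * h * rem)
            rho = u_rem @ rho @ u_rem.conj().T
        if k < 4:
            rho = r180 @ rho @ r180.conj().T

    u_dwell = expm(-1j * h * acq.dwell)
    fid = np.empty(n_points, dtype=complex)
    for k in range(n_points):
        fid[k] = np.trace(fplus @ rho)
        rho = u_dwell @ rho @ u_dwell.conj().T
    return fid / 2.0 ** (n - 2)


def psf_by_direct_convolution(image: np.ndarray, keep: tuple[int, int]) -> np.ndarray:
    """k-space truncation implemented as direct circular convolution with an
    explicitly summed Dirichlet-type kernel (no FFT), the slow-but-obvious
    counterpart of the production masking. Pass-band: |k| <= keep/2 with
    half-weight edges for even extents."""
    ny, nx = image.shape
    ky, kx = keep

    def kernel(n: int, m: int) -> np.ndarray:
        half = m // 2
        out = np.zeros(n)
        for d in range(n):
            acc = 1.0  # k = 0
            for k in range(1, half + 1):
                w = 0.5 if (m % 2 == 0 and k == half) else 1.0
                acc += 2.0 * w * np.cos(2 * np.pi * k * d / n)
            out[d] = acc / n
        return out

    ker_y = kernel(ny, ky)
    ker_x = kernel(nx, kx)
    out = np.zeros_like(image, dtype=float)
    for i in range(ny):
        for j in range(nx):
            acc = 0.0
            for a in range(ny):
                for b in range(nx):
                    acc += image[a, b] * ker_y[(i - a) % ny] * ker_x[(j - b) % nx]
            out[i, j] = acc
    return out


def block_fraction_counts(labels: np.ndarray, block: tuple[int, int], n_classes: int):
    """Brute-force per-voxel class counting for subregion fractions."""
    by, bx = block
    gy, gx = labels.shape[0] // by, labels.shape[1] // bx
    counts = np.zeros((gy, gx, n_classes), dtype=int)
    for i in range(labels.shape[0]):
        for j in range(labels.shape[1]):
            counts[i // by, j // bx, labels[i, j]] += 1
    return counts
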