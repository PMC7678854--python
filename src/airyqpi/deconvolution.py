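"""Richardson-Lucy deconvolution of 3D stacks with a known PSF.

The multiplicative update
``e_{k+1} = e_k * [ (d / (e_k (*) psf)) (*) psf_flipped ]``
is the maximum-likelihood EM iteration for Poisson noise; it preserves
non-negativity and, with a unit-sum PSF, approximately conserves total
intensity.  Boundaries are handled by reflective padding of one PSF extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .image_formation import ImageStack3D


@dataclass(frozen=True)
class DeconvolutionSettings:
    iterations: int = 50
    clip_negatives: bool = True
    epsilon: float = 1e-12  # division guard on the ratio step

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def richardson_lucy(
    stack: ImageStack3D,
    psf: ImageStack3D,
    settings: DeconvolutionSettings | None = None,
) -> ImageStack3D:
    """Deconvolve ``stack`` with ``psf`` for a fixed number of RL iterations."""
    if settings is None:
        settings = DeconvolutionSettings()
    data = stack.voxels
    kernel = np.asarray(psf.voxels, dtype=np.float64)
    if any(ks > ds for ks, ds in zip(kernel.shape, data.shape)):
        raise ValueError(f"PSF shape {kernel.shape} exceeds stack shape {data.shape}")
    total = kernel.sum()
    if total <= 0:
        raise ValueError("PSF must have positive total")
    kernel = kernel / total

    # reflective padding by one PSF extent suppresses wrap-around; the RL
    # update itself runs with cyclic (FFT) convolution, under which a unit-sum
    # PSF conserves total counts exactly on the padded domain and a uniform
    # image is an exact fixed point
    pad = [(s, s) for s in kernel.shape]
    padded = np.pad(data, pad, mode="reflect")
    shape = padded.shape

    kpad = np.zeros(shape)
    kpad[tuple(slice(0, s) for s in kernel.shape)] = kernel
    kpad = np.roll(kpad, [-(s // 2) for s in kernel.shape], axis=(0, 1, 2))
    otf = np.fft.rfftn(kpad)

    def conv(a):
        return np.fft.irfftn(np.fft.rfftn(a) * otf, s=shape, axes=(0, 1, 2))

    def corr(a):  # adjoint: cyclic correlation with the PSF
        return np.fft.irfftn(np.fft.rfftn(a) * np.conj(otf), s=shape, axes=(0, 1, 2))

    estimate = np.full(shape, max(padded.mean(), settings.epsilon))
    for _ in range(settings.iterations):
        model = conv(estimate)
        ratio = padded / np.maximum(model, settings.epsilon)
        estimate = estimate * corr(ratio)
        if settings.clip_negatives:
            np.clip(estimate, 0.0, None, out=estimate)

    sl = tuple(slice(s, s + n) for (s, _), n in zip(pad, data.shape))
    out = estimate[sl]
    return ImageStack3D(np.clip(out, 0.0, None), stack.pitch)


def poisson_log_likelihood(data: np.ndarray, estimate: np.ndarray, psf: np.ndarray,
                           epsilon: float = 1e-12) -> float:
    """Poisson data log-likelihood (up to the data-only constant) of an object
    ``estimate`` under the convolution model: sum d*log(m) - m with
    ``m = estimate (*) psf``.  Used to verify RL's monotone ascent."""
    kernel = psf / psf.sum()
    model = np.maximum(fftconvolve(estimate, kernel, mode="same"), epsilon)
    return float(np.sum(data * np.log(model) - model))
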