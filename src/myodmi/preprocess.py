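"""DWI pre-processing: MP-PCA denoising and isotropic upsampling.

Denoising follows the Marchenko-Pastur PCA scheme: each sliding patch forms a
voxels-by-volumes matrix whose small eigenvalues, for pure noise, fill a
Marchenko-Pastur bulk of width ``4 sigma^2 sqrt(k/n)``; eigenvalues inside
the bulk are discarded and the patch reconstructed from the rest. Patches
overlap and reconstructions are averaged. Upsampling is trilinear per volume
onto an isotropic grid, preserving the field of view.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ValidationError
from .io_formats import DWIStack, ScalarMap


def _mp_denoise_patch(X: np.ndarray):
    """Denoise one patch matrix (n_vox, n_vol); return (X_hat, sigma2, n_noise).

    Eigenvalues of X^T X / n are scanned from the bottom: the largest k whose
    spread fits inside the Marchenko-Pastur bulk for their own variance
    estimate is classified as noise and suppressed.
    """
    n, m = X.shape
    C = (X.T @ X) / n
    vals, vecs = np.linalg.eigh(C)  # ascending
    vals = np.maximum(vals, 0.0)
    n_noise = 0
    sigma2 = 0.0
    for k in range(m, 0, -1):
        var = vals[:k].mean()
        edge = 4.0 * np.sqrt(k / n) * var
        if vals[k - 1] - vals[0] < edge:
            n_noise = k
            sigma2 = var
            break
    keep = np.zeros(m, dtype=bool)
    keep[n_noise:] = True  # n_noise == m suppresses everything (pure noise)
    P = vecs[:, keep] @ vecs[:, keep].T
    return X @ P, sigma2, n_noise


def mppca_denoise(dwi: DWIStack, patch_radius: int = 2, stride: int = 1):
    """MP-PCA denoise a DWI stack.

    Patches are cubes of side ``2 * patch_radius + 1`` shrunk at the image
    boundary; with ``stride`` > 1 patch centers are subsampled (overlap
    averaging still covers every voxel). Returns ``(denoised DWIStack,
    noise-sigma ScalarMap)``. Output intensities are clipped at zero.
    """
    if len(dwi.scheme) < 2:
        raise ValidationError("MP-PCA needs at least 2 volumes")
    if patch_radius < 1:
        raise ValidationError("patch_radius must be >= 1")
    nx, ny, nz, nvol = dwi.data.shape
    accum = np.zeros_like(dwi.data)
    weight = np.zeros((nx, ny, nz))
    sig_accum = np.zeros((nx, ny, nz))
    r = patch_radius

    def centers(n):
        c = list(range(0, n, stride))
        if c[-1] != n - 1:
            c.append(n - 1)
        return c

    for i in centers(nx):
        sx = slice(max(0, i - r), min(nx, i + r + 1))
        for j in centers(ny):
            sy = slice(max(0, j - r), min(ny, j + r + 1))
            for k in centers(nz):
                sz = slice(max(0, k - r), min(nz, k + r + 1))
                patch = dwi.data[sx, sy, sz, :]
                pshape = patch.shape[:3]
                X = patch.reshape(-1, nvol)
                if X.shape[0] < 2:
                    continue
                Xd, sigma2, _ = _mp_denoise_patch(X)
                accum[sx, sy, sz, :] += Xd.reshape(pshape + (nvol,))
                weight[sx, sy, sz] += 1.0
                sig_accum[sx, sy, sz] += np.sqrt(sigma2)

    covered = weight > 0
    out = dwi.data.copy()
    out[covered] = accum[covered] / weight[covered][:, None]
    out = np.clip(out, 0.0, None)
    sigma_map = np.full((nx, ny, nz), np.nan)
    sigma_map[covered] = sig_accum[covered] / weight[covered]
    denoised = DWIStack(data=out, voxel_size=dwi.voxel_size.copy(), scheme=dwi.scheme)
    return denoised, ScalarMap(data=sigma_map, voxel_size=dwi.voxel_size.copy())


def upsample_iso(dwi: DWIStack, target_mm: float = 2.0) -> DWIStack:
    """Trilinear resample every volume onto an isotropic ``target_mm`` grid.

    The field of view (shape times voxel size) is preserved to within one
    voxel; the gradient table is untouched. Already-isotropic input at the
    target resolution passes through with values unchanged.
    """
    if not target_mm > 0:
        raise ValidationError("target_mm must be positive")
    old_vs = dwi.voxel_size
    if np.allclose(old_vs, target_mm):
        return DWIStack(
            data=dwi.data.copy(), voxel_size=old_vs.copy(), scheme=dwi.scheme
        )
    old_shape = np.array(dwi.data.shape[:3])
    new_shape = np.maximum(1, np.round(old_shape * old_vs / target_mm)).astype(int)
    # voxel-center alignment: position (i + 0.5) * vs in mm along each axis
    grids = [
        ((np.arange(n) + 0.5) * target_mm) / old_vs[ax] - 0.5
        for ax, n in enumerate(new_shape)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    coords = np.stack([c.ravel() for c in coords])
    out = np.empty(tuple(new_shape) + (dwi.data.shape[3],))
    for v in range(dwi.data.shape[3]):
        out[..., v] = map_coordinates(
            dwi.data[..., v], coords, order=1, mode="nearest"
        ).reshape(tuple(new_shape))
    out = np.clip(out, 0.0, None)
    return DWIStack(
        data=out,
        voxel_size=np.full(3, float(target_mm)),
        scheme=dwi.scheme,
    )


__all__ = ["mppca_denoise", "upsample_iso"]
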