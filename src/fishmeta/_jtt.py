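"""Jones–Taylor–Thornton (1992) empirical amino-acid substitution model.

The accepted-point-mutation counts (lower triangle, 190 entries) and the
equilibrium amino-acid frequencies are the published JTT values in the
conventional ``ARNDCQEGHILKMFPSTWYV`` residue order.  The instantaneous
rate matrix Q is built as ``Q_ij = s_ij * pi_j`` (i != j) and normalized to
one expected substitution per site per unit time.
"""

from __future__ import annotations

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

# lower-triangle exchangeability counts, column by column
# (A vs R..V, then R vs N..V, ...)
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]

JTT_FREQS = np.array([
    0.076747923252076758, 0.051690948309051694, 0.042644957355042652,
    0.051543948456051550, 0.019802980197019805, 0.040751959248040752,
    0.061829938170061841, 0.073151926848073159, 0.022943977056022944,
    0.053760946239053767, 0.091903908096091905, 0.058675941324058678,
    0.023825976174023829, 0.040125959874040135, 0.050900949099050907,
    0.068764931235068771, 0.058564941435058568, 0.014260985739014262,
    0.032101967898032102, 0.066004933995066004,
])


def exchangeability_matrix() -> np.ndarray:
    s = np.zeros((20, 20))
    it = iter(_JTT_LOWER)
    for j in range(19):
        for i in range(j + 1, 20):
            s[i, j] = s[j, i] = next(it)
    return s


def rate_matrix() -> np.ndarray:
    """Normalized JTT rate matrix (one expected substitution per unit time)."""
    q = exchangeability_matrix() * JTT_FREQS[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(JTT_FREQS * np.diag(q)).sum()
    return q / scale


def spectral_decomposition() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of Q for fast transition matrices.

    Returns (eigenvalues, left, right) such that
    ``P(t) = right @ diag(exp(eigenvalues * t)) @ left``.
    """
    q = rate_matrix()
    d_sqrt = np.sqrt(JTT_FREQS)
    sym = (q * d_sqrt[:, np.newaxis]) / d_sqrt[np.newaxis, :]
    eigval, u = np.linalg.eigh((sym + sym.T) / 2.0)
    right = u / d_sqrt[:, np.newaxis]
    left = u.T * d_sqrt[np.newaxis, :]
    return eigval, left, right
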