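"""The (d+1)-component hypercomplex number system in five lines of algebra.

Builds a few scalars and matrices, checks the defining identities
(conjugate, norm, exact scalar inverse), and shows that d=1 is ordinary
complex arithmetic while d=3 is the four-channel system used for
blue/green/red/NIR palmprint images.
"""

import numpy as np

from hyperelm import HCMatrix, HCScalar, hc_conj, hc_mul, hc_norm, hc_scalar_inv
from hyperelm.hypercomplex import hc_frobenius, hc_matmul, real_embed_solve

y = HCScalar(3.0, [4.0])
print(f"y = {y},  |y| = {hc_norm(y)}")                      # Pythagorean 5
print(f"y * conj(y) = {hc_mul(y, hc_conj(y))}")             # |y|^2, purely real
print(f"y * y^-1 = {hc_mul(y, hc_scalar_inv(y))}")          # exact identity

# d=3: one real slot + three imaginary units, as for 4 spectral bands
q = HCScalar(1.0, [1.0, 1.0, 1.0])                          # the target entry 1+e1+e2+e3
print(f"target entry norm: {hc_norm(q)}")                   # 2 = sqrt(4)

# solving A X = B through the real embedding is exact for every d
rng = np.random.default_rng(0)
A = HCMatrix(rng.normal(size=(4, 6, 6)))
A.components[0] += 6 * np.eye(6)
B = HCMatrix(rng.normal(size=(4, 6, 2)))
X = real_embed_solve(A, B)
residual = hc_frobenius(hc_matmul(A, X) - B) / hc_frobenius(B)
print(f"d=3 linear solve relative residual: {residual:.2e}")
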