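"""Numerator relationship matrix, its sparse inverse, and inbreeding.

A mating of full sibs: the offspring's inbreeding coefficient is 0.25 and
its diagonal element of A is 1.25.  Henderson's rules give the sparse
inverse directly from the pedigree, without forming A.
"""

import numpy as np

from ultravar import Pedigree, build_A, build_A_inverse, inbreeding_coefficients

ped = Pedigree.from_entries(
    [
        ("GS", None, None),
        ("GD", None, None),
        ("S", "GS", "GD"),
        ("D", "GS", "GD"),  # S and D are full sibs
        ("X", "S", "D"),
    ]
)
A = build_A(ped)
F = inbreeding_coefficients(ped)
print("animals:", ped.animals)
print("A =\n", np.round(A, 3))
print("inbreeding:", {a: round(float(f), 3) for a, f in F.items()})

Ainv = build_A_inverse(ped, include_inbreeding=True)
print("A x A^-1 = I?", np.allclose(A @ Ainv.toarray(), np.eye(ped.n), atol=1e-10))
print("F(X) = 0.25: offspring of full sibs share 1/4 of their genes identically by descent")
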