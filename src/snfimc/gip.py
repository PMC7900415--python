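"""Gaussian interaction profile (GIP) kernel similarity.

Every disease is described by its binary interaction profile K(d), the
row of the association matrix recording which miRNAs it is linked to
(columns for miRNAs).  Two entities are similar when their profiles are
close in squared Euclidean (= Hamming, for binary vectors) distance:

    GK(i, j) = exp(-rho * ||K(i) - K(j)||^2)

where the bandwidth rho is the raw bandwidth rho' divided by the mean
squared profile norm, so the kernel scale adapts to the overall density
of the association data.
"""

from __future__ import annotations

import numpy as np

from .containers import AssociationMatrix, SimilarityMatrix


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0) -> float:
    """Normalized kernel bandwidth rho = rho' / mean_i ||K(i)||^2.

    For binary profiles ||K(i)||^2 is the count of ones in row i, an
    exact integer.
    """
    if gamma_prime <= 0:
        raise ValueError(f"gamma_prime must be positive, got {gamma_prime}")
    profiles = np.asarray(profiles, dtype=float)
    mean_sq_norm = float(profiles.sum()) / profiles.shape[0]
    if mean_sq_norm == 0.0:
        raise ValueError("degenerate interaction profiles: all profiles are zero")
    return gamma_prime / mean_sq_norm


def gip_similarity(
    assoc: AssociationMatrix, entity: str, gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """GIP kernel similarity over diseases (rows of A) or miRNAs (columns).

    Symmetric with unit diagonal; every entry lies in (0, 1].  Entities
    with identical profiles (including two all-zero profiles) get
    similarity exactly 1.
    """
    if entity == "disease":
        profiles, ids = assoc.values, assoc.disease_ids
    elif entity == "mirna":
        profiles, ids = assoc.values.T, assoc.mirna_ids
    else:
        raise ValueError(f"entity must be 'disease' or 'mirna', got {entity!r}")
    rho = gip_bandwidth(profiles, gamma_prime)
    # binary profiles: ||x - y||^2 = |x| + |y| - 2 x.y, all exact integers
    counts = profiles.sum(axis=1)
    sq_dist = counts[:, None] + counts[None, :] - 2.0 * (profiles @ profiles.T)
    np.fill_diagonal(sq_dist, 0.0)
    values = np.exp(-rho * sq_dist)
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, list(ids), view_name="gip")
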