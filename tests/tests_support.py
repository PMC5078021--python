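"""Shared helpers for building synthetic inputs in tests."""

import numpy as np

from tlsea.core import AssociationResult, BackgroundSamples, ProteinAssociation


def normal_background_samples(k, a, b, n_lengths, reps, rng, lo=1, hi=10_000):
    """Background samples drawn straight from the generative moment model
    Normal(k*m, a*m**b) at distinct random lengths m."""
    ms = rng.choice(np.arange(lo, hi + 1), size=n_lengths, replace=False)
    lengths = np.repeat(ms, reps)
    values = rng.normal(k * lengths, a * lengths.astype(float) ** b)
    return BackgroundSamples(lengths, values, 0.15)


def result_with_pz(pz_by_protein, col_ids=None):
    """AssociationResult carrying a given per-protein P_Z layout."""
    pz_by_protein = {pid: np.asarray(v, dtype=float) for pid, v in pz_by_protein.items()}
    n = len(next(iter(pz_by_protein.values())))
    col_ids = col_ids or [f"c{i}" for i in range(n)]
    proteins = [
        ProteinAssociation(pid, 10, np.zeros(n), np.zeros(n), pz, 0.0, 1.0)
        for pid, pz in pz_by_protein.items()
    ]
    return AssociationResult(col_ids, proteins, c=2.0, pz_resolution=1e-5,
                             po_resolution=1e-5)
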