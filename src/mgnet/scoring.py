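"""Drug-disease association scores and permutation calibration.

A drug and the disease are each summarized by a per-term p-value profile:
the drug's raw drug-term p on every term adjacent to it in the bipartite
drug-term network, and the disease's raw enrichment p on every significant
term.  The association score over the shared terms is

    S = -log10( sum_k P_drug,k * P_disease,k )

so small p-values on both sides drive S up.  S alone is not comparable
across drugs (its scale depends on how many and which terms a drug
touches), so it is standardized against a permutation null: the disease
profile's p-values are shuffled across its term labels (the drug's term
adjacency stays fixed), S is recomputed per shuffle, and

    Z = (S - mean(S_null)) / sd(S_null).

Drugs with Z > 1.96 (one-sided P < 0.05 under a normal null) are the
screening candidates.  An exact mode enumerates all permutations of small
profiles and serves as the oracle for the Monte-Carlo sampler.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .enrichment import EnrichmentRecord
from .errors import InputError, ScoreError
from .dgofn import BipartiteNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PValueProfile",
    "AssociationResult",
    "make_profiles",
    "association_score",
    "permutation_z",
    "select_candidates",
]

P_FLOOR = 1e-300  # applied on profile construction; guards log/products


@dataclass(frozen=True)
class PValueProfile:
    """Entity (drug or disease) -> per-term p-values, floored at 1e-300."""

    entity: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        floored = {}
        for term, p in self.values.items():
            if not (0.0 <= p <= 1.0):
                raise InputError(f"p-value {p} for term {term} outside [0, 1]")
            floored[term] = max(float(p), P_FLOOR)
        object.__setattr__(self, "values", floored)

    def terms(self) -> set[str]:
        return set(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class AssociationResult:
    """Observed S, its permutation null moments, and the resulting Z."""

    drug: str
    S: float
    perm_mean: float
    perm_std: float
    Z: float | None
    n_perm: int
    mode: str
    seed: int

    @property
    def z_defined(self) -> bool:
        return self.Z is not None


def make_profiles(
    dgofn: BipartiteNetwork,
    disease_enrichment: list[EnrichmentRecord],
    disease_label: str = "disease",
) -> tuple[dict[str, PValueProfile], PValueProfile]:
    """Build per-drug and disease p-value profiles from the upstream stages.

    Each drug's profile spans exactly the terms adjacent to it in the
    drug-term network (raw edge p); the disease profile spans all
    significant enrichment terms (raw enrichment p).
    """
    graph = dgofn.graph
    drug_profiles: dict[str, PValueProfile] = {}
    for drug in dgofn.drugs:
        values = {
            term: graph.edges[drug, term]["p"] for term in graph.neighbors(drug)
        }
        if not values:
            logger.warning("drug %s has no edges; excluded from scoring", drug)
            continue
        drug_profiles[drug] = PValueProfile(entity=drug, values=values)
    if not drug_profiles:
        logger.warning("empty drug-term network: no drug profiles to score")
    disease_values = {
        rec.term: rec.p for rec in disease_enrichment if rec.significant
    }
    disease_profile = PValueProfile(entity=disease_label, values=disease_values)
    return drug_profiles, disease_profile


def _shared_vectors(
    drug: PValueProfile, disease: PValueProfile
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Sorted disease domain, its value vector, shared indices, drug vector."""
    domain = sorted(disease.values)
    disease_vec = np.array([disease.values[t] for t in domain])
    shared = [t for t in domain if t in drug.values]
    if not shared:
        raise ScoreError(
            f"drug {drug.entity} shares no terms with the disease profile"
        )
    idx = np.array([domain.index(t) for t in shared], dtype=int)
    drug_vec = np.array([drug.values[t] for t in shared])
    return domain, disease_vec, idx, drug_vec


def association_score(drug: PValueProfile, disease: PValueProfile) -> float:
    """S = -log10 of the summed p-value products over shared terms."""
    _, disease_vec, idx, drug_vec = _shared_vectors(drug, disease)
    total = float(np.dot(drug_vec, disease_vec[idx]))
    return -math.log10(max(total, P_FLOOR))


def permutation_z(
    drug: PValueProfile,
    disease: PValueProfile,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "monte-carlo",
    perm_domain: str = "full",
) -> AssociationResult:
    """Standardize S against shuffled disease-profile assignments.

    ``perm_domain="full"`` (default) shuffles the disease p-values across
    the disease profile's whole term vector before re-reading the shared
    positions — a drug pointing at the *most* significant disease terms
    scores above its null.  ``perm_domain="shared"`` shuffles within the
    shared set only.  ``mode="exact"`` enumerates every permutation of the
    domain vector (domain size <= 8) and is the Monte-Carlo oracle; its
    moments are population moments over the complete enumeration, while
    Monte-Carlo uses the sample (n-1) standard deviation.

    A constant disease profile makes every shuffle identical; the result
    then carries ``Z=None`` rather than raising.
    """
    _, disease_vec, idx, drug_vec = _shared_vectors(drug, disease)
    S_obs = -math.log10(max(float(np.dot(drug_vec, disease_vec[idx])), P_FLOOR))

    if perm_domain == "full":
        pool = disease_vec
        positions = idx
    elif perm_domain == "shared":
        pool = disease_vec[idx]
        positions = np.arange(len(idx))
    else:
        raise InputError(f"unknown permutation domain {perm_domain!r}")

    if mode == "exact":
        if len(pool) > 8:
            raise InputError(
                f"exact mode enumerates {len(pool)}! permutations; domain must be <= 8"
            )
        sums = np.array(
            [
                float(np.dot(drug_vec, np.asarray(perm)[positions]))
                for perm in permutations(pool)
            ]
        )
        S_null = -np.log10(np.maximum(sums, P_FLOOR))
        n_used = len(S_null)
        perm_mean = float(S_null.mean())
        perm_std = float(S_null.std(ddof=0))
    elif mode == "monte-carlo":
        if n_perm < 2:
            raise InputError("n_perm must be >= 2")
        rng = np.random.default_rng(seed)
        mat = np.tile(pool, (n_perm, 1))
        rng.permuted(mat, axis=1, out=mat)
        sums = mat[:, positions] @ drug_vec
        S_null = -np.log10(np.maximum(sums, P_FLOOR))
        n_used = n_perm
        perm_mean = float(S_null.mean())
        perm_std = float(S_null.std(ddof=1))
    else:
        raise InputError(f"unknown mode {mode!r}")

    if perm_std == 0.0:
        logger.warning(
            "degenerate permutation null for %s (constant scores); Z undefined",
            drug.entity,
        )
        Z = None
    else:
        Z = (S_obs - perm_mean) / perm_std
    return AssociationResult(
        drug=drug.entity,
        S=S_obs,
        perm_mean=perm_mean,
        perm_std=perm_std,
        Z=Z,
        n_perm=n_used,
        mode=mode,
        seed=seed,
    )


def select_candidates(
    results: list[AssociationResult], z_threshold: float = 1.96
) -> list[AssociationResult]:
    """Drugs with defined Z strictly above the threshold, strongest first."""
    hits = [r for r in results if r.Z is not None and r.Z > z_threshold]
    hits.sort(key=lambda r: (-r.Z, r.drug))
    return hits
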