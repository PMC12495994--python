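"""Higher-order, structure-consistent negative sampling.

A negative sample keeps the biological structure of a real ceRNA triplet:
starting from a known positive, the miRNA is held fixed, the lncRNA and
mRNA may be swapped for other validated partners of that same miRNA, and
the disease is drawn from those not linked to the triplet.  Negatives
never overlap the positive set, and a per-disease quota keeps the disease
marginal of the negatives close to that of the positives.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import NamedTuple

import numpy as np

__all__ = ["TripletSample", "SamplerExhaustedError", "candidate_diseases", "sample_negatives"]


class TripletSample(NamedTuple):
    """One (lncRNA, miRNA, mRNA, disease, label) record."""

    lnc: str
    mi: str
    mr: str
    dis: str
    label: int


class SamplerExhaustedError(RuntimeError):
    """Raised when the candidate space cannot supply the requested count."""

    def __init__(self, requested, produced, attempts):
        self.requested, self.produced, self.attempts = requested, produced, attempts
        super().__init__(
            f"negative sampler exhausted after {attempts} attempts: "
            f"produced {produced} of {requested} requested negatives"
        )


def candidate_diseases(triplet, positives, all_diseases) -> set:
    """Diseases not positively associated with the given (lnc, mi, mr).

    An empty result flags a fully-associated triplet; the sampler responds
    by re-drawing its seed triplet.
    """
    all_diseases = set(all_diseases)
    if not all_diseases:
        raise ValueError("empty disease universe")
    l, m, r = triplet[:3]
    taken = {p.dis if isinstance(p, TripletSample) else p[3]
             for p in positives
             if (p[0], p[1], p[2]) == (l, m, r)}
    return all_diseases - taken


def sample_negatives(
    positives,
    lnc_mi_edges,
    mi_mr_edges,
    all_diseases,
    n: int,
    seed: int = 0,
    exclude=None,
    max_attempts_factor: int = 100,
) -> list:
    """Draw ``n`` structure-consistent negatives (label 0).

    Every negative's lncRNA-miRNA and miRNA-mRNA links exist in the input
    edge lists, its miRNA equals that of a uniformly drawn seed positive,
    and the quadruple appears in neither the positives nor ``exclude``.
    Seed positives are drawn uniformly, so the miRNA marginal of the
    negatives tracks the positives'; a per-disease quota of
    ceil(2n / #diseases-in-positives) bounds disease skew.  Fully
    reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    positives = [TripletSample(*p[:4], 1) for p in positives]
    if not positives:
        raise ValueError("no positive samples to seed from")
    lnc_partners: dict = {}
    mr_partners: dict = {}
    for l, m in lnc_mi_edges:
        lnc_partners.setdefault(m, []).append(l)
    for m, r in mi_mr_edges:
        mr_partners.setdefault(m, []).append(r)
    if not lnc_partners or not mr_partners:
        raise ValueError("interaction edge lists must be non-empty")
    for m in lnc_partners:
        lnc_partners[m] = sorted(set(lnc_partners[m]))
    for m in mr_partners:
        mr_partners[m] = sorted(set(mr_partners[m]))

    diseases = sorted(set(all_diseases))
    pos_keys = {(p.lnc, p.mi, p.mr, p.dis) for p in positives}
    forbidden = set(pos_keys)
    if exclude:
        forbidden |= {tuple(e[:4]) for e in exclude}

    # precomputed candidate structure: triplet -> diseases already positive
    taken_by_triplet: dict = {}
    for p in positives:
        taken_by_triplet.setdefault((p.lnc, p.mi, p.mr), set()).add(p.dis)

    n_dis_in_pos = len({p.dis for p in positives})
    quota = math.ceil(2 * n / max(n_dis_in_pos, 1))
    per_disease = Counter()

    rng = np.random.default_rng(seed)
    out: list = []
    chosen: set = set()
    attempts = 0
    max_attempts = max_attempts_factor * n
    fully_associated = 0
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise SamplerExhaustedError(n, len(out), attempts - 1)
        p = positives[rng.integers(len(positives))]
        m = p.mi
        lp = lnc_partners.get(m)
        rp = mr_partners.get(m)
        if not lp or not rp:
            continue
        l = lp[rng.integers(len(lp))]
        r = rp[rng.integers(len(rp))]
        taken = taken_by_triplet.get((l, m, r))
        if taken is None:
            cand = diseases
        else:
            cand = [d for d in diseases if d not in taken]
            if not cand:
                fully_associated += 1  # re-draw the seed triplet
                continue
        d = cand[rng.integers(len(cand))]
        key = (l, m, r, d)
        if key in forbidden or key in chosen:
            continue
        if per_disease[d] >= quota:
            continue
        chosen.add(key)
        per_disease[d] += 1
        out.append(TripletSample(l, m, r, d, 0))
    return out
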