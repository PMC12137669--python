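"""Shared fixtures: a brute-force isotope-envelope oracle and small pools."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from oligoms.chemistry import ELEMENT_ORDER, ISOTOPES, ElementalFormula


def enumerate_envelope(f: ElementalFormula, prune: float = 1e-6, merge_tol: float = 0.01):
    """Exhaustive multinomial expansion of a formula's isotopologues.

    Independent of the convolution implementation: enumerates every way of
    assigning isotopes to the atoms of each element, with multinomial
    weights, then merges peaks closer than *merge_tol*, prunes below *prune*
    relative abundance, and renormalises.  Only feasible for small formulas.
    """
    per_element = []
    for elem, count in zip(ELEMENT_ORDER, f.counts):
        if count == 0:
            continue
        isotopes = ISOTOPES[elem]
        options = []
        # partitions of `count` atoms among the isotopes of this element
        for split in itertools.product(range(count + 1), repeat=len(isotopes) - 1):
            rest = count - sum(split)
            if rest < 0:
                continue
            ks = (rest,) + split
            weight = math.factorial(count)
            for k, (_, ab) in zip(ks, isotopes):
                weight = weight / math.factorial(k) * ab**k
            mass = sum(k * m for k, (m, _) in zip(ks, isotopes))
            options.append((mass, weight))
        per_element.append(options)
    masses, weights = [0.0], [1.0]
    for options in per_element:
        masses = [m + om for m in masses for om, _ in options]
        weights = [w * ow for w in weights for _, ow in options]
    masses = np.array(masses)
    weights = np.array(weights)
    order = np.argsort(masses)
    masses, weights = masses[order], weights[order]
    # merge within merge_tol: consecutive gaps below the tolerance coalesce
    # into abundance-weighted centroids (the grouping rule of a centroided
    # instrument; same semantics as the envelope under test)
    groups = []
    cur = [0]
    for i in range(1, masses.size):
        if masses[i] - masses[i - 1] < merge_tol:
            cur.append(i)
        else:
            groups.append(cur)
            cur = [i]
    groups.append(cur)
    cm = np.array([np.average(masses[g], weights=weights[g]) for g in groups])
    ca = np.array([weights[g].sum() for g in groups])
    keep = ca >= prune * ca.sum()
    cm, ca = cm[keep], ca[keep]
    return cm, ca / ca.sum()


@pytest.fixture
def envelope_oracle():
    return enumerate_envelope
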