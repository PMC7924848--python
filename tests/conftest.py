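import itertools

import numpy as np
import pandas as pd
import pytest

from lipaflow.cohort import AvdVector
from lipaflow.io import AbundanceTable, EnzymeProfileSet, GramAnnotation
from lipaflow.pathway import PATHWAY_ENZYMES, build_default_pathway


@pytest.fixture(scope="session")
def model():
    return build_default_pathway()


@pytest.fixture(scope="session")
def all_enzyme_subsets():
    """All 512 subsets of the nine pathway enzymes."""
    subsets = []
    for r in range(len(PATHWAY_ENZYMES) + 1):
        subsets.extend(frozenset(c) for c in itertools.combinations(PATHWAY_ENZYMES, r))
    return subsets


def brute_force_terminal(enzymes, model):
    """Independent prefix walker: try every prefix 1..k explicitly.

    A prefix is viable when each of its steps is present or skippable and
    its last step's enzyme is literally present; the terminal product is
    the deepest viable prefix's product.
    """
    best = None
    for k in range(1, len(model.steps) + 1):
        prefix = model.steps[:k]
        viable = all(
            s.enzyme in enzymes or s.enzyme in model.skip_allowed for s in prefix
        ) and prefix[-1].enzyme in enzymes
        if viable:
            best = prefix[-1].product
    return best if best is not None else "NO-PATHWAY"


def random_avd(rng, n_taxa=20, group="case", prefix="T"):
    """A random AVD vector over n_taxa taxa summing to 100."""
    raw = rng.dirichlet(np.ones(n_taxa)) * 100.0
    taxa = [f"{prefix}{i:03d}" for i in range(n_taxa)]
    return AvdVector(group=group, values=pd.Series(raw, index=taxa))


def random_annotation(rng, taxa):
    statuses = rng.choice(["negative", "positive", "unknown"], size=len(taxa))
    return GramAnnotation(dict(zip(taxa, statuses)))


def random_profiles(rng, taxa, include_mods=False):
    enzymes = list(PATHWAY_ENZYMES) + (["LpxE", "LpxF"] if include_mods else [])
    return EnzymeProfileSet(
        {
            t: {e: float(rng.uniform(0, 100)) for e in enzymes}
            for t in taxa
        }
    )


def make_table(values, groups, taxa=None, samples=None):
    """AbundanceTable from a plain nested list."""
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    taxa = taxa or [f"T{i:03d}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=samples, columns=taxa)
    labels = pd.Series(groups, index=samples)
    return AbundanceTable(df, labels).normalize()
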