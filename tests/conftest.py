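import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from translatomics.expression import ExpressionMatrix
from translatomics.features import SequenceFeaturizer, assemble_transcripts
from translatomics.simulate import SimulationParams, simulate_all

# tiny forests on tiny samples legitimately leave some rows without OOB votes
warnings.filterwarnings(
    "ignore", message="Some inputs do not have OOB scores"
)


def make_expression(
    values: dict[tuple[str, str], list[float]] | None = None,
    genes: list[str] | None = None,
    n_reps: int = 3,
    rng: np.random.Generator | None = None,
    sigma: float = 0.0,
    fractions: tuple[str, ...] = ("total", "monosome", "polysome"),
) -> ExpressionMatrix:
    """Small expression matrix builder: per-(condition, fraction) cell
    means, shared across genes, plus optional iid noise."""
    genes = genes or ["g1", "g2"]
    rng = rng or np.random.default_rng(0)
    rows = []
    for cond in ("control", "stress"):
        for frac in fractions:
            base = values.get((cond, frac), 8.0) if values else 8.0
            for rep in range(1, n_reps + 1):
                for i, gene in enumerate(genes):
                    mean = base[i] if isinstance(base, (list, np.ndarray)) else base
                    noise = rng.normal(0, sigma) if sigma else 0.0
                    rows.append((gene, cond, frac, rep, mean + noise))
    df = pd.DataFrame(
        rows,
        columns=["gene", "condition", "fraction", "replicate", "log2_intensity"],
    )
    return ExpressionMatrix.from_long(df)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic benchmark shared across tests (600 genes)."""
    params = SimulationParams(
        n_genes=600, regulon_size=80, up_regulon_size=60, seed=11
    )
    return simulate_all(params)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Assembled transcripts + fitted featurizer + matrix for the small set."""
    records, dropped = assemble_transcripts(
        small_dataset.records, small_dataset.regions
    )
    featurizer = SequenceFeaturizer()
    X = featurizer.fit_transform(records, expression=small_dataset.expression)
    return {"records": records, "dropped": dropped, "featurizer": featurizer,
            "X": X}
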