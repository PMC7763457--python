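import numpy as np
import pytest

from qsartrees import DescriptorSchema, DescriptorTable, FeatureSpec, SyntheticSpec, generate


@pytest.fixture
def toy_table():
    """Four samples, one continuous + one flag feature, separable on x1."""
    schema = DescriptorSchema((("x1", "continuous"), ("x2", "flag")))
    values = np.array([[1.0, 0], [2.0, 1], [3.0, 0], [4.0, 1]])
    labels = np.array(["RB", "RB", "NRB", "NRB"])
    return DescriptorTable(values, labels, schema)


@pytest.fixture
def imbalanced_table():
    """Small 2:1 imbalanced table with one strong continuous feature."""
    spec = SyntheticSpec(
        n_pos=30,
        n_neg=60,
        features=(
            FeatureSpec(kind="continuous", effect=1.5),
            FeatureSpec(kind="ordinal", effect=0.0),
            FeatureSpec(kind="flag", effect=0.0),
            FeatureSpec(kind="continuous", effect=0.0),
        ),
        seed=42,
    )
    return generate(spec)


def small_informative_spec(seed: int, n_per_class: int = 40, p_noise: int = 5,
                           effect: float = 2.0) -> SyntheticSpec:
    """One informative continuous feature (first) plus continuous noise."""
    feats = [FeatureSpec(kind="continuous", effect=effect)]
    feats += [FeatureSpec(kind="continuous", effect=0.0) for _ in range(p_noise)]
    return SyntheticSpec(
        n_pos=n_per_class, n_neg=n_per_class, features=tuple(feats), seed=seed
    )
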