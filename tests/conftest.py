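import numpy as np
import pytest

from crtimbalance.design import ImbalanceSpec, TrialDesign, rho_xz_from_k
from crtimbalance.design import imbalance_quantile
from crtimbalance.simulate import TrialData


def make_design(n1: int, n2: int, k: int, q: float = 0.5) -> TrialDesign:
    """Design with intervention clusters first and k covariate-positive
    clusters in the intervention arm."""
    half = n2 // 2
    x = np.zeros(n2, dtype=np.int64)
    x[:half] = 1
    z = np.zeros(n2, dtype=np.int64)
    z[:k] = 1
    z[half : half + (half - k)] = 1
    return TrialDesign(
        n1=n1, n2=n2, x=x, z=z,
        imbalance=ImbalanceSpec(q=q, k=k, rho_xz=rho_xz_from_k(n2, k)),
    )


def make_design_at_quantile(n1: int, n2: int, q: float) -> TrialDesign:
    return make_design(n1, n2, imbalance_quantile(n2, q), q)


@pytest.fixture
def toy_trial() -> TrialData:
    """Four clusters of two subjects with hand-computable ANOVA quantities.

    Cluster outcomes {1,3}, {2,4}, {3,5}, {6,8} on x=(0,0,1,1), z=(0,1,0,1):
    within SS = 8 on 4 df, cluster means (2,3,4,7).
    """
    design = TrialDesign(
        n1=2,
        n2=4,
        x=np.array([0, 0, 1, 1]),
        z=np.array([0, 1, 0, 1]),
        imbalance=ImbalanceSpec(q=0.5, k=1, rho_xz=0.0),
    )
    y = np.array([[1.0, 3.0], [2.0, 4.0], [3.0, 5.0], [6.0, 8.0]])
    return TrialData(design=design, y=y)
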