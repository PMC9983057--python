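import numpy as np
import pytest
from scipy.special import expit

import ipsi


@pytest.fixture
def spec05():
    return ipsi.multiplicative_shift(0.5)


@pytest.fixture
def j1_law():
    """Point-treatment law: L ~ Ber(0.5), f(1|l) = 0.4, m(1, l) = 0.9,
    m(0, l) = 0.5, indication everywhere; exact psi(0.5) = 0.78 by hand."""
    return ipsi.DiscreteLaw(
        J=1, levels=[0.0, 1.0],
        p_l=lambda j, l, lh, ah: 0.5,
        f1=lambda j, lh, ah: 0.4,
        surv=lambda j, lh, ah: 0.9 if ah[-1] == 1 else 0.5,
        lstar_of=lambda l: 1.0,
    )


def _j2_p_l(j, l, lh, ah):
    if j == 0:
        return 0.5
    p1 = expit(-0.3 + 0.8 * lh[0] - 0.5 * ah[0])
    return p1 if l == 1 else 1.0 - p1


@pytest.fixture
def j2_law():
    """Two-interval binary-covariate law with moderate probabilities (all
    history cells well populated at a few hundred subjects)."""
    return ipsi.DiscreteLaw(
        J=2, levels=[0.0, 1.0],
        p_l=_j2_p_l,
        f1=lambda j, lh, ah: 0.4 + 0.2 * lh[-1] if j == 0
        else float(expit(-0.4 + 0.6 * lh[1] + 0.5 * ah[0])),
        surv=lambda j, lh, ah: float(
            expit(0.3 + 0.7 * ah[-1] - 0.6 * lh[-1]
                  + 0.3 * (ah[0] if j == 1 else 0))
        ),
    )


#: full-history saturated working models for J=2 discrete panels
J2_SAT_TREATMENT = ["L", "L + Alag + L_lag + L:Alag + L:L_lag + Alag:L_lag "
                    "+ L:Alag:L_lag"]
J2_SAT_OUTCOME = ["A + L + A:L",
                  "A + L + Alag + L_lag + A:L + A:Alag + A:L_lag + L:Alag "
                  "+ L:L_lag + Alag:L_lag + A:L:Alag + A:L:L_lag "
                  "+ A:Alag:L_lag + L:Alag:L_lag + A:L:Alag:L_lag"]


@pytest.fixture
def toy_panel():
    """Two subjects, J = 2, one death at interval 1."""
    Y = np.array([[1.0, 1, 1], [1, 0, 0]])
    C = np.zeros((2, 3))
    A = np.array([[1.0, 0], [0, np.nan]])
    L = np.array([[1.0, 0], [0, np.nan]])
    return ipsi.PanelData(covariates={"lstar": L}, lstar="lstar",
                          A=A, C=C, Y=Y)


def manual_panel(lstar, A, C, Y):
    return ipsi.PanelData(covariates={"lstar": np.asarray(lstar, float)},
                          lstar="lstar", A=np.asarray(A, float),
                          C=np.asarray(C, float), Y=np.asarray(Y, float))
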