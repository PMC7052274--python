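import math

import numpy as np
import pytest

from forcemap.bayes_core import NaturalParameters


def make_natural_parameters(zeta_par=0.0, zeta_perp=0.0, zeta_sp=0.0,
                            n=100, d=2, u=1.0, V_eff=0.05, dt=0.04):
    """Construct NaturalParameters directly from dimensionless inputs."""
    n_pi = 4 if d == 1 else 3
    zeta_sp_vec = np.zeros(d)
    zeta_sp_vec[0] = zeta_sp
    zeta_t = np.zeros(d)
    if d == 1:
        # one axis only: whichever component the caller gave is the drift
        zeta_t[0] = zeta_par + zeta_perp
    else:
        zeta_t[0] = zeta_par
        zeta_t[1] = zeta_perp
    sp = abs(zeta_sp)
    t2 = float(zeta_t @ zeta_t)
    if sp > 0:
        par = float(zeta_t @ zeta_sp_vec) / sp
        perp = math.sqrt(max(t2 - par**2, 0.0))
    else:
        par, perp = math.sqrt(t2), 0.0
    return NaturalParameters(
        zeta_t=zeta_t, zeta_sp=zeta_sp_vec, zeta_par=par, zeta_perp=perp,
        eta=math.sqrt(n_pi / (n + n_pi)), v=1.0 + n_pi * u / n,
        kappa=d * (n + n_pi - 1) / 2.0 - 1.0,
        m=d * (n_pi - 1) / 2.0 - 1.0, n=n, d=d, V_eff=V_eff, dt=dt)


@pytest.fixture
def rng():
    return np.random.default_rng(20240511)


@pytest.fixture
def trajectory_csv(tmp_path):
    """Three 2D trajectories, the second with a missing frame: 8 rows total."""
    path = tmp_path / "traj.csv"
    path.write_text(
        "traj_id,frame,x,y\n"
        "a,0,0.00,0.00\n"
        "a,1,0.10,0.00\n"
        "a,2,0.20,0.05\n"
        "b,0,0.50,0.50\n"
        "b,1,0.55,0.45\n"
        "b,3,0.60,0.40\n"     # frame 2 missing: the 1->3 pair is a gap
        "c,0,0.90,0.10\n"
        "c,1,0.85,0.15\n")
    return path
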