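import numpy as np
import pytest

from mrkit.harmonize import HarmonizedInstrument
from mrkit.sumstats import SummaryAssociation, load_fixture


def make_instruments(beta_exp, beta_out, se_exp=0.01, se_out=0.01):
    """Build harmonized instruments from parallel effect arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_exp = np.broadcast_to(np.asarray(se_exp, dtype=float), beta_exp.shape)
    se_out = np.broadcast_to(np.asarray(se_out, dtype=float), beta_exp.shape)
    return [
        HarmonizedInstrument(
            variant_id=f"rs{i + 1}", beta_exp=float(ge), se_exp=float(se),
            beta_out=float(go), se_out=float(so), eaf_exp=0.3, eaf_out=0.3)
        for i, (ge, go, se, so) in enumerate(zip(beta_exp, beta_out, se_exp, se_out))
    ]


def random_instruments(rng, j=10, theta=0.3, gamma_sd=0.1, min_gamma=0.05,
                       se_exp=0.003, se_out=0.01, alpha=None):
    """Instruments drawn from the linear IV model with optional direct effects."""
    gamma = rng.normal(0, gamma_sd, j)
    small = np.abs(gamma) < min_gamma
    gamma[small] = np.sign(gamma[small] + (gamma[small] == 0)) * min_gamma
    alpha = np.zeros(j) if alpha is None else np.asarray(alpha, dtype=float)
    gamma_hat = rng.normal(gamma, se_exp)
    Gamma_hat = rng.normal(theta * gamma + alpha, se_out)
    return make_instruments(gamma_hat, Gamma_hat, se_exp, se_out)


def make_assoc(variant_id="rs1", chrom="1", pos=1000, effect_allele="A",
               other_allele="G", eaf=0.3, beta=0.1, se=0.01, pvalue=1e-10,
               **kw) -> SummaryAssociation:
    return SummaryAssociation(variant_id=variant_id, chrom=chrom, pos=pos,
                              effect_allele=effect_allele, other_allele=other_allele,
                              eaf=eaf, beta=beta, se=se, pvalue=pvalue, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240119)


@pytest.fixture(scope="session")
def ea_caffeine_instruments():
    """Single-variant caffeine->eGFR instrument from the packaged EA table."""
    from mrkit.harmonize import harmonize_pair
    recs = load_fixture("ea_caffeine_pair")
    exp = [r for r in recs if r.trait == "plasma caffeine"]
    out = [r for r in recs if r.trait == "eGFRcre"]
    return harmonize_pair(exp, out)


@pytest.fixture(scope="session")
def eu_caffeine_instruments():
    """Two-variant caffeine->eGFR instruments from the packaged EU table."""
    from mrkit.harmonize import harmonize_pair
    recs = load_fixture("eu_caffeine_pair")
    exp = [r for r in recs if r.trait == "plasma caffeine"]
    out = [r for r in recs if r.trait == "eGFRcre"]
    return harmonize_pair(exp, out)
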