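import pytest
from hypothesis import HealthCheck, settings

from zymoflux import build_reference_model

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return build_reference_model()


#: the published wild-type-constrained flux column, 2-decimal values.
#: ATPM and the biomass drain are not printed; tests derive them from the
#: printed column (biomass drain = biomass export; ATPM closes ATP).
PRINTED_COLUMN_A = {
    "GLK": 1.00, "PGI": 0.01, "G6PDH_nadp": 0.99, "PGL": 0.99, "EDD": 0.99,
    "KDPGA": 0.99, "GAPDH": 0.98, "PGK": 0.98, "PGM": 0.96, "ENO": 0.96,
    "PYK": 0.94, "PDC": 1.80, "ADH": 0.68, "ACDH_nad": 0.07,
    "RNDH_nadh": 0.40, "RNDH_nadph": 0.77, "UO": 0.58, "TKT2": -0.01,
    "RPE": 0.01, "RPI": 0.01, "PDH": 0.03, "EX_glc": -1.00, "EX_o2": -0.58,
    "EX_biomass": 0.01, "EX_co2": 1.89, "EX_e4p": 0.01, "EX_ethanol": 0.68,
    "EX_acetate": 0.07, "EX_acetoin": 0.06, "EX_acetaldehyde": 0.99,
}


def complete_printed_column(column: dict[str, float]) -> dict[str, float]:
    """Fill the unprinted internal fluxes from the printed ones."""
    full = dict(column)
    full["BIOMASS_RXN"] = column["EX_biomass"]
    # lumped carboligase is acetoin's only source
    full["ACTNS"] = column["EX_acetoin"]
    # ATP balance: PGK + PYK - GLK - 30 x biomass drain
    full["ATPM"] = (
        column["PGK"] + column["PYK"] - column["GLK"] - 30 * full["BIOMASS_RXN"]
    )
    return full
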