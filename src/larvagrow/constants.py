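"""Reference constants for *Arenicola marina* early-life-stage bioenergetics.

Values come from laboratory rearing experiments on lugworm larvae at 13, 15
and 17°C and from the standard Dynamic Energy Budget (DEB) temperature
machinery.  They serve as package-wide defaults; every consumer accepts
overrides.
"""

#: Mean fertilized-oocyte diameter, μm — default length at t = 0.
DEFAULT_L0_UM = 176.0

#: Age at first exogenous feeding ("birth" in DEB terms), days
#: post-fertilization, per rearing temperature (°C).
T_B_BY_TEMPERATURE = {13.0: 21.0, 15.0: 17.0, 17.0: 17.0}

#: Anatomically observed body-length window at first feeding, μm.
BIRTH_LENGTH_WINDOW_UM = (450.0, 500.0)

#: DEB reference temperature, K (20°C).
T_REF_K = 293.15

#: Arrhenius temperature above the upper tolerance boundary, K, estimated
#: from juvenile/adult metabolic rates; held fixed when re-estimating the
#: larval correction curve.
T_AH_K = 82380.0

#: Larval-stage Arrhenius temperature re-estimated from standardized
#: embryonic/larval rates, K, with its standard error.
LARVAL_T_A_K = 6661.79
LARVAL_T_A_SE_K = 1241.5

#: Larval-stage upper boundary of the thermal tolerance range, K, with SE.
LARVAL_T_H_K = 294.44
LARVAL_T_H_SE_K = 0.42

#: Juvenile/adult thermal parameters (prior estimate), K.
ADULT_T_A_K = 4014.0
ADULT_T_H_K = 297.7

#: Temperatures (°C) at which standardized rate data are available: the
#: three rearing temperatures plus the fertilization-assay temperatures.
RATE_CURVE_TEMPERATURES_C = (5.0, 10.0, 13.0, 15.0, 17.0, 18.0, 20.0, 22.0)

#: Food-condition labels used throughout.
FED = "fed"
NON_FED = "non_fed"
PRE_BIRTH = "pre_birth"
FOOD_LABELS = (FED, NON_FED, PRE_BIRTH)
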