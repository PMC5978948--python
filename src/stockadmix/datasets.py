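"""Published summary tables from the Québec Brook Charr stocking study.

Three small tables are bundled because the downstream statistics are defined
against them: the 29-lake sampling/admixture summary (per-lake sample sizes
and mean domestic membership q-domestic), the covariate dictionary with the
observed range of each predictor, and the per-population SNP retention counts
after each filtering step. The raw genotype archive itself is not bundled;
synthetic data (:mod:`stockadmix.synthdata`) stands in for it.
"""

from __future__ import annotations

import io

import pandas as pd

# Reserve, lake, abbreviation, stocking years, sampling year, n sampled,
# n genotyped, hatchery strain, mean domestic membership +/- SD.
_LAKES_CSV = """\
reserve,lake,abbrev,initial_stocking,final_stocking,sampling_year,n_sampled,n_genotyped,strain,q_domestic,q_sd
Mastigouche,Abenakis,ABE,1977,2006,2014,22,21,TM,0.135,0.235
Mastigouche,Arbout,ARB,1973,1980,2014,30,28,TM,0.042,0.182
Mastigouche,Chamberlain,CHA,1972,2006,2014,23,20,TM,0.107,0.113
Mastigouche,Cougouar,COU,1975,1995,2014,30,29,TM,0.046,0.078
Mastigouche,Deux-Etapes,DET,1972,2012,2014,30,28,TM,0.046,0.081
Mastigouche,Gelinotte,GEL,1992,2012,2014,30,25,TM,0.060,0.135
Mastigouche,Grignon,GRI,1977,2013,2014,26,24,TM,0.037,0.072
Mastigouche,Jones,JON,1975,1989,2014,30,26,TM,0.098,0.240
Mastigouche,Ledoux,LED,1971,1989,2014,30,27,TM,0.017,0.031
Mastigouche,Lemay,LEM,1974,1980,2014,30,28,TM,0.018,0.041
Portneuf,Amanites,AMA,1979,2012,2014,30,29,JC,0.061,0.136
Portneuf,Caribou,CAR,2008,2013,2014,25,23,JC,0.196,0.238
Portneuf,Daphnies,DAP,1998,2012,2014,28,27,JC,0.138,0.302
Portneuf,Duhamel,DUH,1969,2009,2014,23,21,JC,0.013,0.030
Portneuf,Methot,MET,1980,2013,2014,30,29,JC,0.312,0.328
Saint-Maurice,Brown,BRO,1966,1975,2015,40,28,TM,0.069,0.099
Saint-Maurice,Brulot,BRU,1970,1972,2015,33,25,TM,0.044,0.076
Saint-Maurice,Corbeil,COR,1969,1971,2015,30,23,TM,0.033,0.067
Saint-Maurice,Gaspard,GAS,1970,1971,2015,34,31,TM,0.061,0.101
Saint-Maurice,Maringouins,MAR,1970,1990,2015,30,26,TM,0.052,0.092
Saint-Maurice,Melchior,MEL,1970,1971,2015,30,27,TM,0.045,0.066
Saint-Maurice,Milord,MIL,1969,2005,2015,30,25,TM,0.098,0.123
Saint-Maurice,Perdu,PER,1964,1990,2015,30,24,TM,0.154,0.175
Saint-Maurice,Porc-Epic,POE,1969,1978,2015,31,26,TM,0.012,0.022
Saint-Maurice,Portage,POR,1979,1990,2015,30,27,TM,0.019,0.042
Saint-Maurice,Soucis,SOU,1976,1976,2015,31,22,TM,0.151,0.201
Saint-Maurice,Tempete,TEM,1964,2009,2015,21,18,TM,0.138,0.162
Saint-Maurice,A la Truite,TRU,1968,1982,2015,30,24,TM,0.090,0.122
Saint-Maurice,Vierge,VIE,1967,1968,2015,45,29,TM,0.001,0.008
"""

# SNP counts surviving each filtering stage, per lake x domestic-strain pair.
_SNP_RETENTION_CSV = """\
abbrev,after_populations,after_biallelic,after_custom,first_snp_per_locus
ABE,284759,96397,6151,5138
ARB,296552,98419,5994,5073
CHA,291366,99135,6194,5163
COU,297918,98967,5935,5026
DET,301417,98150,5646,4809
GEL,295149,97650,5585,4736
GRI,298066,99269,5743,4850
JON,291407,96360,5978,4980
LED,292153,97791,5549,4675
LEM,285727,96602,5227,4421
AMA,330263,114990,5628,4846
CAR,332548,116255,5449,4729
DAP,336816,116131,5575,4828
DUH,337362,116884,6043,5136
MET,346929,120031,5402,4661
BRO,318864,113456,5683,4689
BRU,321773,114659,4961,4102
COR,333200,115494,5192,4319
GAS,285780,99625,5820,4743
MAR,329718,115383,5193,4286
MEL,311428,110727,5474,4512
MIL,345176,122426,5007,4130
PER,355382,124537,4822,4003
POE,355712,125789,4916,4053
POR,373935,129871,5085,4058
SOU,337661,119059,4521,3750
TEM,326046,116146,4867,4026
TRU,283111,99871,6092,4941
VIE,355839,118522,4969,4125
"""

#: Environmental predictors of the lake covariate table.
ENVIRONMENT_VARIABLES = ("LakeSize", "Depth", "MeanTemp", "MeanO2", "MeanpH")

#: Stocking-intensity predictors, including the time-since-stocking variable.
STOCKING_VARIABLES = ("TotalHa", "NbStockEv", "MeanFishStock", "SinceMeanYear")

#: All nine candidate predictors of mean domestic membership.
PREDICTOR_VARIABLES = ENVIRONMENT_VARIABLES + STOCKING_VARIABLES

#: Observed (minimum, maximum, median) of each predictor over the 29 lakes.
PREDICTOR_RANGES: dict[str, tuple[float, float, float]] = {
    "LakeSize": (5.0, 273.0, 10.0),
    "Depth": (2.56, 29.26, 10.85),
    "MeanTemp": (16.90, 24.52, 19.92),
    "MeanO2": (4.76, 8.10, 6.17),
    "MeanpH": (6.03, 7.6, 6.77),
    "TotalHa": (114.47, 4660.5, 1072.58),
    "NbStockEv": (1.0, 38.0, 9.0),
    "MeanFishStock": (259.0, 750000.0, 1637.5),
    "SinceMeanYear": (3.45, 47.5, 31.75),
}


def load_lake_summary() -> pd.DataFrame:
    """Per-lake sampling effort and mean domestic membership (q-domestic)."""
    return pd.read_csv(io.StringIO(_LAKES_CSV))


def load_snp_retention() -> pd.DataFrame:
    """SNP counts after each filtering stage for the 29 population pairs."""
    return pd.read_csv(io.StringIO(_SNP_RETENTION_CSV))
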