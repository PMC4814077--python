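import pytest

from snakebite_cea import load_assumptions, load_country_table

# Published per-country results: base-case ICER per DALY averted, cost per
# death averted, and the five scenario ICERs (antivenom cost $125, $306,
# carpet-viper proportion 0, non-CV effectiveness 0, comparator cost $65.63).
PUBLISHED_RESULTS = {
    "benin": (82.63, 1997.91, 72.87, 135.96, 81.75, 97.26, 59.75),
    "burkina_faso": (99.44, 2384.81, 87.98, 164.05, 226.53, 107.18, 71.94),
    "cameroon": (86.97, 2030.05, 76.70, 143.11, 238.39, 92.01, 62.89),
    "chad": (136.94, 3070.80, 120.77, 225.34, 376.61, 144.89, 99.03),
    "cote_divoire": (128.24, 2916.02, 113.09, 211.04, 278.37, 139.16, 92.73),
    "gambia": (150.08, 3628.88, 132.25, 247.47, 261.77, 229.59, 108.30),
    "ghana": (103.61, 2532.73, 91.38, 170.50, 227.63, 111.21, 74.93),
    "guinea_bissau": (87.09, 2032.72, 76.75, 143.60, 84.76, 226.64, 62.85),
    "guinea_conakry": (83.54, 1997.41, 73.67, 137.49, 82.68, 100.72, 60.40),
    "liberia": (256.61, 6204.95, 226.00, 423.92, 261.77, 13964.26, 184.85),
    "mali": (160.48, 3836.74, 141.52, 264.06, 243.47, 178.09, 116.04),
    "niger": (97.23, 2351.06, 85.75, 159.99, 261.77, 102.98, 70.31),
    "nigeria": (92.56, 2160.33, 81.61, 152.35, 232.04, 107.96, 66.91),
    "senegal": (143.81, 3515.25, 126.73, 237.14, 258.95, 216.41, 103.78),
    "sierra_leone": (280.77, 6204.95, 247.27, 463.83, 286.42, 15278.99, 202.25),
    "togo": (120.42, 2878.98, 106.19, 198.14, 264.75, 129.25, 87.08),
}


@pytest.fixture(scope="session")
def countries():
    return load_country_table()


@pytest.fixture(scope="session")
def by_id(countries):
    return {cp.country_id: cp for cp in countries}


@pytest.fixture(scope="session")
def assumptions():
    return load_assumptions()


@pytest.fixture(scope="session")
def ga(assumptions):
    return assumptions[0]


@pytest.fixture(scope="session")
def ci(assumptions):
    return assumptions[1]


@pytest.fixture(scope="session")
def benin(by_id):
    return by_id["benin"]
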