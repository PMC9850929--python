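"""Published summary values used as test oracles.

Masses are kg/capita/yr (mean, SD); an SD of 0 marks a point estimate.
Per-capita emissions are (mean, SD) in kg/capita/yr per species; national
totals in kg/yr; percent increases in %.
"""

# Per-capita daily generation rates (kg/person/day), all households / burners only.
DAILY_PC_ALL = (3.34e-2, 1.58e-2)
DAILY_PC_BURNERS = (2.66e-2, 1.32e-2)

# Per-capita generation bounds (kg/capita/yr).
LOWER_PC = (12.2, 5.8)
UPPER_PC = 29.3

# City-level generation and burn fractions.
CITY_GENERATION = {"Guatemala city": 28.1, "Jutiapa": 15.4}
CITY_BURN_FRACTION = {"Guatemala city": 0.280, "Jutiapa": 0.875}
CITY_BURNED_PC = {"Guatemala city": 7.87, "Jutiapa": 13.5}

# Department lower-bound burned masses (mean, SD) and printed upper bounds.
DEPT_LOWER = {"Jalapa": (6.04, 2.86), "Jutiapa": (7.44, 3.52),
              "Guatemala": (1.26, 0.594)}
DEPT_UPPER = {"Jalapa": 14.5, "Jutiapa": 17.9, "Guatemala": 3.02}

# National burned plastic mass (kg/yr).
NATIONAL_BURNED = {"lower": 80.2e6, "upper": 193e6}

SPECIES = ("PM2.5", "BC", "OC", "CO", "CO2")

# Per-capita emission estimates (kg/capita/yr): (mean, sd) per species.
PER_CAPITA_EMISSIONS = {
    "Xalapan": {
        "PM2.5": (0.813, 0.425), "BC": (0.100, 5.08e-2), "OC": (0.485, 0.250),
        "CO": (0.384, 0.398), "CO2": (25.1, 12.5),
    },
    "Jutiapa city": {
        "PM2.5": (1.13, 0.171), "BC": (0.139, 1.40e-2), "OC": (0.671, 8.88e-2),
        "CO": (0.531, 0.434), "CO2": (34.8, 2.11),
    },
    "Guatemala city": {
        "PM2.5": (0.659, 0.100), "BC": (8.12e-2, 8.17e-3), "OC": (0.393, 5.20e-2),
        "CO": (0.310, 0.254), "CO2": (20.3, 1.24),
    },
    "Department of Jalapa (lower)": {
        "PM2.5": (0.505, 0.254), "BC": (6.23e-2, 3.03e-2), "OC": (0.301, 0.149),
        # the CO2 SD cell is printed as 0.747 in the source table, an apparent
        # factor-of-10 slip: the product-of-normals closed form gives 7.47
        "CO": (0.238, 0.243), "CO2": (15.6, 7.47),
    },
    "Department of Jutiapa (lower)": {
        "PM2.5": (0.623, 0.313), "BC": (7.67e-2, 3.73e-2), "OC": (0.371, 0.184),
        "CO": (0.293, 0.300), "CO2": (19.2, 9.19),
    },
    "Department of Guatemala (lower)": {
        "PM2.5": (0.105, 5.25e-2), "BC": (1.30e-2, 6.26e-3), "OC": (6.28e-2, 3.09e-2),
        "CO": (4.96e-2, 5.06e-2), "CO2": (3.25, 1.54),
    },
    "Department of Jalapa (upper)": {
        "PM2.5": (1.21, 0.184), "BC": (0.150, 1.51e-2), "OC": (0.723, 9.58e-2),
        "CO": (0.571, 0.468), "CO2": (37.5, 2.28),
    },
    "Department of Jutiapa (upper)": {
        "PM2.5": (1.50, 0.227), "BC": (0.185, 1.86e-2), "OC": (0.893, 0.118),
        "CO": (0.705, 0.577), "CO2": (46.3, 2.81),
    },
    "Department of Guatemala (upper)": {
        "PM2.5": (0.253, 3.85e-2), "BC": (3.11e-2, 3.14e-3), "OC": (0.151, 2.00e-2),
        "CO": (0.119, 9.73e-2), "CO2": (7.81, 0.474),
    },
}

# Burned plastic mass (mean, sd) underlying each per-capita emission row.
ROW_MASSES = {
    "Xalapan": (2.66e-2 * 365, 1.32e-2 * 365),
    "Jutiapa city": (15.4 * 0.875, 0.0),
    "Guatemala city": (28.1 * 0.280, 0.0),
    "Department of Jalapa (lower)": (6.04, 2.86),
    "Department of Jutiapa (lower)": (7.44, 3.52),
    "Department of Guatemala (lower)": (1.26, 0.594),
    "Department of Jalapa (upper)": (14.5, 0.0),
    "Department of Jutiapa (upper)": (17.9, 0.0),
    "Department of Guatemala (upper)": (3.02, 0.0),
}

# National totals (mean, sd) in kg/yr per bound and species.
NATIONAL_TOTALS = {
    "lower": {
        "PM2.5": (6.71e6, 3.37e6), "BC": (8.27e5, 4.02e5), "OC": (4.00e6, 1.98e6),
        "CO": (3.16e6, 3.23e6), "CO2": (2.07e8, 9.90e7),
    },
    "upper": {
        "PM2.5": (1.61e7, 2.46e6), "BC": (1.99e6, 2.01e5), "OC": (9.62e6, 1.28e6),
        "CO": (7.61e6, 6.21e6), "CO2": (4.99e8, 3.03e7),
    },
}

# National inventory baseline (kg in 2015).
INVENTORY = {"PM2.5": 1.19e8, "BC": 1.45e7, "OC": 5.54e7, "CO": 2.05e9,
             "CO2": 3.68e10}

# Printed percent increases (mean, sd) per bound and species.
PERCENT_INCREASE = {
    "lower": {
        "PM2.5": (5.62, 2.82), "BC": (5.70, 2.77), "OC": (7.23, 3.58),
        "CO": (0.154, 0.157), "CO2": (0.564, 0.369),
    },
    "upper": {
        "PM2.5": (13.5, 2.06), "BC": (13.7, 1.38), "OC": (17.4, 2.30),
        "CO": (0.371, 0.303), "CO2": (1.36, 8.25e-2),
    },
}

# Survey weekly masses (mean, sd) in kg, weeks 1-4.
WEEKLY = ((1.31, 0.66), (1.12, 0.91), (0.92, 0.70), (0.99, 0.77))

BURN_HOUSEHOLD_FRACTION = 0.84
BURN_MASS_FRACTION = 0.80

RURAL_R2 = 0.63
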