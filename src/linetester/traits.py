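"""Default trait list for the cauliflower trial: 16 agronomic traits with
units and the breeder's desirable direction (``-`` for earliness/core
length, ``+`` for size and yield traits). Trait names are free strings;
this list is only a convenient default."""

DEFAULT_TRAITS = {
    # abbr: (description, unit, desirable direction)
    "CI": ("days to 50% curd initiation", "days", "-"),
    "CM": ("days to 50% curd maturity", "days", "-"),
    "PH": ("plant height", "cm", "+"),
    "GPW": ("gross plant weight", "g", "+"),
    "MCW": ("marketable curd weight", "g", "+"),
    "NCW": ("net curd weight", "g", "+"),
    "LL": ("leaf length", "cm", "+"),
    "LW": ("leaf width", "cm", "+"),
    "NoL": ("number of leaves", "count", "+"),
    "CL": ("curd length", "cm", "+"),
    "CD": ("curd diameter", "cm", "+"),
    "CoL": ("core length", "cm", "-"),
    "CSI": ("curd size index", "cm^2", "+"),
    "LSI": ("leaf size index", "cm^2", "+"),
    "HI": ("harvest index", "%", "+"),
    "TMY": ("total marketable yield", "t/ha", "+"),
}

TRAIT_NAMES = list(DEFAULT_TRAITS)

DESIRABLE_DIRECTION = {k: v[2] for k, v in DEFAULT_TRAITS.items()}
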