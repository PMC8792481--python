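"""Static ISO 3166-1 alpha-2 country codes and informal-name aliases.

The CITES Trade Database and conservation literature mix formal ISO codes
with informal country names ("RSA", "DRC"); this module provides a
validation set and an alias table so both are accepted on input while all
internal bookkeeping uses alpha-2 codes.
"""

from __future__ import annotations

#: Officially assigned ISO 3166-1 alpha-2 codes.
ISO_ALPHA2: frozenset[str] = frozenset(
    """
    AD AE AF AG AI AL AM AO AQ AR AS AT AU AW AX AZ
    BA BB BD BE BF BG BH BI BJ BL BM BN BO BQ BR BS BT BV BW BY BZ
    CA CC CD CF CG CH CI CK CL CM CN CO CR CU CV CW CX CY CZ
    DE DJ DK DM DO DZ EC EE EG EH ER ES ET FI FJ FK FM FO FR
    GA GB GD GE GF GG GH GI GL GM GN GP GQ GR GS GT GU GW GY
    HK HM HN HR HT HU ID IE IL IM IN IO IQ IR IS IT
    JE JM JO JP KE KG KH KI KM KN KP KR KW KY KZ
    LA LB LC LI LK LR LS LT LU LV LY
    MA MC MD ME MF MG MH MK ML MM MN MO MP MQ MR MS MT MU MV MW MX MY MZ
    NA NC NE NF NG NI NL NO NP NR NU NZ OM
    PA PE PF PG PH PK PL PM PN PR PS PT PW PY QA RE RO RS RU RW
    SA SB SC SD SE SG SH SI SJ SK SL SM SN SO SR SS ST SV SX SY SZ
    TC TD TF TG TH TJ TK TL TM TN TO TR TT TV TW TZ
    UA UG UM US UY UZ VA VC VE VG VI VN VU WF WS YE YT ZA ZM ZW
    """.split()
)

#: Pseudo-codes used by the CITES Trade Database for unknown / various origins.
CITES_PSEUDO_CODES: frozenset[str] = frozenset({"XX", "XV", "ZZ"})

#: Informal names → ISO alpha-2. Keys are matched case-insensitively after
#: stripping punctuation; only names that actually occur in lion trade and
#: conservation sources are listed.
COUNTRY_ALIASES: dict[str, str] = {
    "RSA": "ZA",
    "SOUTH AFRICA": "ZA",
    "DRC": "CD",
    "DEMOCRATIC REPUBLIC OF THE CONGO": "CD",
    "DR CONGO": "CD",
    "CONGO DR": "CD",
    "TANZANIA": "TZ",
    "UNITED REPUBLIC OF TANZANIA": "TZ",
    "SWAZILAND": "SZ",
    "ESWATINI": "SZ",
    "IVORY COAST": "CI",
    "COTE DIVOIRE": "CI",
    "CAR": "CF",
    "CENTRAL AFRICAN REPUBLIC": "CF",
    "UAE": "AE",
    "USA": "US",
    "UK": "GB",
    "SOUTH SUDAN": "SS",
    "SUDAN": "SD",
    "ETHIOPIA": "ET",
    "ZAMBIA": "ZM",
    "MALAWI": "MW",
    "MOZAMBIQUE": "MZ",
    "ZIMBABWE": "ZW",
    "BOTSWANA": "BW",
    "NAMIBIA": "NA",
    "ANGOLA": "AO",
    "KENYA": "KE",
    "UGANDA": "UG",
    "SOMALIA": "SO",
    "RWANDA": "RW",
    "GABON": "GA",
    "INDIA": "IN",
    "SENEGAL": "SN",
    "BENIN": "BJ",
    "NIGER": "NE",
    "NIGERIA": "NG",
    "BURKINA FASO": "BF",
    "CAMEROON": "CM",
    "CHAD": "TD",
    "UNKNOWN": "XX",
}


def normalize_country(value: str, *, allow_pseudo: bool = False) -> str:
    """Return the ISO alpha-2 code for ``value`` (code or informal name).

    Raises ``ValueError`` for anything that is neither a valid code nor a
    known alias. CITES pseudo-codes (XX, ...) are accepted only when
    ``allow_pseudo`` is true.
    """
    if not isinstance(value, str) or not value.strip():
        raise ValueError(f"not a country code: {value!r}")
    key = value.strip().upper().replace(".", "").replace("'", "")
    code = COUNTRY_ALIASES.get(key, key)
    if code in ISO_ALPHA2:
        return code
    if allow_pseudo and code in CITES_PSEUDO_CODES:
        return code
    raise ValueError(f"unknown country code or name: {value!r}")
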