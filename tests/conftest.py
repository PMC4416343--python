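import pytest
from hypothesis import HealthCheck, settings

from classfx import AdeVocabulary, DrugVocabulary

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# log-PRRs of the SSRI class members against sexual dysfunctions, the
# worked example of the class-effect decision rule
SSRI_LOG_PRRS = {
    "fluoxetine": 4.25,
    "fluvoxamine": 3.85,
    "sertraline": 3.68,
    "citalopram": 3.57,
    "paroxetine": 3.77,
    "escitalopram": 3.57,
}


@pytest.fixture
def ssri_log_prrs():
    return dict(SSRI_LOG_PRRS)


@pytest.fixture
def drug_vocab():
    """Small realistic drug terminology: PIN aliasing and a dual-code drug."""
    return DrugVocabulary(
        term_to_ingredient={
            "D_ofloxacin": "ofloxacin",
            "D_valproic_acid": "valproic acid",  # precise ingredient (salt form)
            "D_rosuvastatin_C422923": "301542",
            "D_cipro": "ciprofloxacin",
            "D_norflox": "norfloxacin",
            "D_pefl": "pefloxacin",
        },
        pin_to_in={"valproic acid": "valproate"},
        ingredient_to_codes={
            "ofloxacin": {"J01MA01", "S01AE01"},
            "ciprofloxacin": {"J01MA02"},
            "norfloxacin": {"J01MA06"},
            "pefl": set(),
            "pefloxacin": {"J01MA03"},
            "301542": {"C10AA07"},
            "valproate": {"N03AG01"},
        },
        code_to_class={
            "J01MA01": ("J01MA", "Fluoroquinolones"),
            "J01MA02": ("J01MA", "Fluoroquinolones"),
            "J01MA03": ("J01MA", "Fluoroquinolones"),
            "J01MA06": ("J01MA", "Fluoroquinolones"),
            "S01AE01": ("S01AE", "Fluoroquinolones (ophthalmological)"),
            "C10AA07": ("C10AA", "HMG CoA reductase inhibitors"),
            "N03AG01": ("N03AG", "Fatty acid derivatives"),
        },
    )


@pytest.fixture
def ade_vocab():
    """Small MeSH-like manifestation hierarchy."""
    return AdeVocabulary(
        term_to_trees={
            "Tendinopathy": {"C05.651.869"},
            "Rhabdomyolysis": {"C05.651.807"},
            "Muscular Diseases": {"C05.651"},
            "Drug-induced liver injury": {"C06.552.195"},
            "Liver Diseases": {"C06.552"},
            "Long QT": {"C14.280.123", "C23.550.073"},
            "Heart Diseases": {"C14.280"},
            "Pathological Signs": {"C23.550"},
        },
        tree_to_term={
            "C05.651.869": "Tendinopathy",
            "C05.651.807": "Rhabdomyolysis",
            "C05.651": "Muscular Diseases",
            "C06.552.195": "Drug-induced liver injury",
            "C06.552": "Liver Diseases",
            "C14.280.123": "Long QT",
            "C23.550.073": "Long QT",
            "C14.280": "Heart Diseases",
            "C23.550": "Pathological Signs",
        },
    )
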