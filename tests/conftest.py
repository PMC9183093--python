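import pytest

from botakey.traitbase import TaxonRow, TraitMatrix, default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture()
def tiny_flora(schema):
    """Three legumes with a constructed discriminant: only one yellow corolla."""
    rows = [
        TaxonRow("Lotus corniculatus", {
            "corolla_color": frozenset({"yellow"}),
            "height_min": 10.0, "height_max": 40.0,
            "flowering_since": 4, "flowering_until": 7,
            "habitat": frozenset({"grassland", "roadsides"}),
            "other_notes": "windswept cliffs near the sea",
        }),
        TaxonRow("Trifolium pratense", {
            "corolla_color": frozenset({"pink", "purple"}),
            "height_min": 10.0, "height_max": 40.0,
            "flowering_since": 11, "flowering_until": 2,  # wraps the year
            "leaflet_count_min": 3, "leaflet_count_max": 3,
        }),
        TaxonRow("Medicago sativa", {
            "corolla_color": frozenset({"purple", "blue"}),
            "height_min": 30.0, "height_max": 80.0,
            "flowering_since": 5, "flowering_until": 9,
            "altitude_min": 0.0, "altitude_max": 1200.0,
        }),
    ]
    return TraitMatrix(schema=schema, rows=rows)
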