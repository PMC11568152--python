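"""Versioned schema for the machine-readable pipeline report."""

from __future__ import annotations

REPORT_SCHEMA_VERSION = "1"

_SUMMARY_KEYS = {"name", "map", "hdi_low", "hdi_high", "pd", "rope_pct"}
_TOP_LEVEL = {"schema_version", "h1_specialization", "h2_richness",
              "h3_beta_diversity", "h4_difference_of_differences",
              "descriptives", "provenance"}


class ReportSchemaError(ValueError):
    """A report dict does not conform to the declared schema version."""


def _check_summary(d: dict, where: str) -> None:
    if not isinstance(d, dict) or not _SUMMARY_KEYS <= set(d):
        raise ReportSchemaError(
            f"{where}: summary row missing keys {_SUMMARY_KEYS - set(d)}")


def validate_report(report: dict) -> None:
    """Raise :class:`ReportSchemaError` unless the dict matches the schema.

    Every summary row must carry pd and rope_pct; provenance must record the
    seed and the per-taxon exclusion counts.
    """
    missing = _TOP_LEVEL - set(report)
    if missing:
        raise ReportSchemaError(f"missing top-level keys: {sorted(missing)}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ReportSchemaError(
            f"unsupported schema version {report['schema_version']!r}")
    for taxon, rows in report["h1_specialization"].items():
        for row in rows:
            _check_summary(row, f"h1[{taxon}]")
    for taxon, d in report["h2_richness"].items():
        for key in ("averaged_elevation_effect", "percent_change_per_sd"):
            _check_summary(d[key], f"h2[{taxon}].{key}")
    for taxon, rows in report["h3_beta_diversity"].items():
        for row in rows:
            _check_summary(row, f"h3[{taxon}]")
    for taxon, rows in report["h4_difference_of_differences"].items():
        for row in rows:
            _check_summary(row, f"h4[{taxon}]")
    prov = report["provenance"]
    for key in ("seed", "config", "config_hash", "exclusions",
                "package_version"):
        if key not in prov:
            raise ReportSchemaError(f"provenance missing {key!r}")
    for taxon, ex in prov["exclusions"].items():
        for key in ("species_sd_zero", "empty_union_pairs_dropped"):
            if key not in ex:
                raise ReportSchemaError(
                    f"exclusions[{taxon}] missing {key!r}")
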