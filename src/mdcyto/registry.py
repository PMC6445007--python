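"""The 21-parameter physical-phenotype registry.

Every cell measured by the pipeline is summarised by a fixed, ordered set
of 21 named scalars grouped into four categories: size, deformability,
morphology, and deformation kinetics.  Ten of these extend the classic
deformability-cytometry pair (mean diameter, maximum deformation) with
area-based size measures, baseline-corrected deformability, radial
morphology scores, and frame-to-frame kinetics of the aspect ratio D(t).

The registry is the single source of truth for feature names, ordering,
units and provenance; feature tables, classifiers and the embedding all
validate against it.
"""

from __future__ import annotations

from dataclasses import dataclass

REGISTRY_VERSION = "1.0"

CATEGORIES = ("size", "deformability", "morphology", "kinetics")


@dataclass(frozen=True)
class ParameterInfo:
    """Metadata for one phenotype parameter.

    provenance is "paper" for parameters named by the original m-DC
    parameter set and "artifact" for documented reconstructions that
    complete the 21-slot registry.
    """

    name: str
    category: str
    unit: str
    provenance: str
    description: str


REGISTRY: tuple[ParameterInfo, ...] = (
    # -- size ------------------------------------------------------------
    ParameterInfo(
        "mean_diameter", "size", "px", "paper",
        "2/360 * sum_theta r_membrane(theta): average diameter of the "
        "resting cell from its radial profile."),
    ParameterInfo(
        "area", "size", "px^2", "paper",
        "Polygon (shoelace) area of the 360-vertex radial contour; robust "
        "to cell shape."),
    ParameterInfo(
        "perimeter", "size", "px", "artifact",
        "Closed polyline length of the radial contour."),
    ParameterInfo(
        "equivalent_diameter", "size", "px", "artifact",
        "sqrt(4*area/pi): diameter of the circle with the same area."),
    # -- deformability ---------------------------------------------------
    ParameterInfo(
        "max_deformation", "deformability", "unitless", "paper",
        "Peak aspect ratio D_max = max_t l_vertical/l_horizontal during "
        "deformation."),
    ParameterInfo(
        "relative_deformability", "deformability", "unitless", "paper",
        "D_max / D_0: peak deformation relative to the aspect ratio prior "
        "to deformation instead of a circular baseline."),
    ParameterInfo(
        "deformation_gain", "deformability", "unitless", "artifact",
        "D_max - D_0: additive deformation above the resting aspect ratio."),
    ParameterInfo(
        "size_normalized_deformation", "deformability", "1/px", "paper",
        "D_max / equivalent_diameter: peak deformation normalised by cell "
        "size."),
    ParameterInfo(
        "final_deformation", "deformability", "unitless", "artifact",
        "Aspect ratio D at the last usable frame (post-relaxation)."),
    # -- morphology ------------------------------------------------------
    ParameterInfo(
        "surface_roughness_5deg", "morphology", "px", "paper",
        "sum_theta |r_membrane(theta) - MA_5(theta)| with a short (5 deg) "
        "trailing moving average: high-frequency boundary structure."),
    ParameterInfo(
        "cell_shape_30deg", "morphology", "px", "paper",
        "sum_theta |r_membrane(theta) - MA_30(theta)| with a long (30 deg) "
        "trailing moving average: low-frequency shape deviation."),
    ParameterInfo(
        "initial_aspect_ratio", "morphology", "unitless", "paper",
        "Aspect ratio D_0 of the cell prior to deformation."),
    ParameterInfo(
        "circularity", "morphology", "unitless", "artifact",
        "4*pi*area/perimeter^2; 1 for a circle."),
    ParameterInfo(
        "normalized_roughness", "morphology", "unitless", "artifact",
        "surface_roughness_5deg divided by the mean radius (scale-free)."),
    ParameterInfo(
        "normalized_shape", "morphology", "unitless", "artifact",
        "cell_shape_30deg divided by the mean radius (scale-free)."),
    # -- kinetics --------------------------------------------------------
    ParameterInfo(
        "mean_deformation_rate", "kinetics", "1/us", "paper",
        "Mean of positive per-step rates (D(t)-D(t-1))/dt; 0 if the aspect "
        "ratio never increases."),
    ParameterInfo(
        "mean_relaxation_rate", "kinetics", "1/us", "paper",
        "Mean of negative per-step rates; <= 0, 0 if no relaxation is "
        "observed."),
    ParameterInfo(
        "max_deformation_rate", "kinetics", "1/us", "artifact",
        "Largest per-step rate of change of D(t)."),
    ParameterInfo(
        "min_deformation_rate", "kinetics", "1/us", "artifact",
        "Smallest (most negative) per-step rate of change of D(t)."),
    ParameterInfo(
        "time_to_max_deformation", "kinetics", "us", "artifact",
        "Elapsed time from the first usable frame to the frame of D_max."),
    ParameterInfo(
        "net_deformation_change", "kinetics", "unitless", "paper",
        "sum_t D(t)-D(t-1), which telescopes to D_end - D_0."),
)

FEATURE_NAMES: tuple[str, ...] = tuple(p.name for p in REGISTRY)

#: the two parameters measured by the original deformability cytometry
#: system; classification baselines start from this pair.
BASELINE_FEATURES: tuple[str, str] = ("mean_diameter", "max_deformation")

NEW_FEATURES: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES if n not in BASELINE_FEATURES)

_BY_NAME = {p.name: p for p in REGISTRY}


def parameter_info(name: str) -> ParameterInfo:
    """Look up registry metadata for one parameter name."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown phenotype parameter {name!r}; registry has "
            f"{len(FEATURE_NAMES)} parameters") from None


def category_features(category: str) -> tuple[str, ...]:
    """All registry names in one of the four categories."""
    if category not in CATEGORIES:
        raise KeyError(f"unknown category {category!r}; one of {CATEGORIES}")
    return tuple(p.name for p in REGISTRY if p.category == category)


def validate_feature_names(names) -> list[str]:
    """Check that every name is in the registry; return them as a list."""
    names = list(names)
    unknown = [n for n in names if n not in _BY_NAME]
    if unknown:
        raise KeyError(f"names not in the phenotype registry: {unknown}")
    return names


def registry_metadata() -> dict:
    """JSON-ready sidecar describing the registry (version, units, tags)."""
    return {
        "registry_version": REGISTRY_VERSION,
        "n_parameters": len(REGISTRY),
        "parameters": [
            {"name": p.name, "category": p.category, "unit": p.unit,
             "provenance": p.provenance}
            for p in REGISTRY
        ],
    }


assert len(REGISTRY) == 21, "phenotype registry must have exactly 21 entries"
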