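"""tigermove: acoustic-telemetry movement-network analysis.

Detection QC, residency statistics, growth-corrected life staging,
per-individual movement networks with motility (node/edge density)
metrics, random-network null tests, and AIC-based selection among
smooth models of motility versus body size — plus a synthetic
detection simulator so the whole chain runs with known ground truth.
"""

from .growth import (
    DEFAULT_SCHEDULE,
    DEFAULT_SCHEME,
    GrowthSchedule,
    LifeStageScheme,
    classify_life_stage,
    estimate_fl_at,
    restage_cohort,
)
from .io import filter_false_detections, read_detections, read_receivers, read_tags
from .models import (
    CANDIDATE_SPECS,
    REFERENCE_EDGE_DENSITY_AIC,
    cohort_ttest_fl_by_sex,
    fit_candidates,
    model_selection_table,
    select_model,
    smooth_summary,
)
from .network import (
    MovementNetwork,
    active_stations,
    build_network,
    build_networks,
    compare_to_null,
    count_movers,
    motility,
    node_metrics,
    random_network_null,
)
from .pipeline import build_motility_records, run_cohort, write_bundle
from .residency import (
    monthly_summary,
    occupancy,
    residency_index,
    residency_summary,
    station_residency_runs,
    to_detection_days,
)
from .simulate import (
    SimConfig,
    TruthRecord,
    emit_detections,
    simulate_array,
    simulate_cohort_and_tracks,
    true_movement_counts,
)
from .stats import akaike_weights, wilcoxon_signed_rank

__version__ = "0.1.0"


def percent_time_outside(mean_residency_index: float) -> float:
    """Percent of the monitoring period spent outside the arrays."""
    if not 0.0 <= mean_residency_index <= 1.0:
        raise ValueError("residency index must lie in [0, 1]")
    return (1.0 - mean_residency_index) * 100.0
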