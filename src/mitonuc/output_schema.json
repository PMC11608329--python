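{
  "organelles.csv": {
    "label": "positive integer organelle id, raster order of first pixel",
    "area_um2": "mask area times pixel area, um^2",
    "length_um": "skeleton geodesic diameter plus end-cap correction, um",
    "centroid_x_um": "centroid x (column direction), um",
    "centroid_y_um": "centroid y (row direction), um",
    "cluster_count": "number of nucleoid clusters assigned to this organelle",
    "flags": "semicolon-joined subset of {too_long, empty, edge_touching}",
    "included_longitudinal": "true if the organelle passed the longitudinal filters"
  },
  "clusters.csv": {
    "cluster_id": "1-based id, sorted by descending integrated intensity",
    "x_um": "centroid x, um",
    "y_um": "centroid y, um",
    "peak": "maximum raw pixel value in the cluster footprint",
    "integrated": "background-subtracted (top-hat) intensity sum over footprint",
    "diameter_um": "diameter of a disk with the footprint's area, um",
    "organelle_label": "owning organelle id, empty if unassigned",
    "arc_position": "normalized [0,1] position along the owning organelle's midline"
  },
  "summary.json": "per-cell array and longitudinal statistics, colocalization when computed, and all parameters used",
  "run_report.json": "package version, all parameters affecting results, SHA-256 of every input file",
  "truth_organelles.csv": {
    "label": "true organelle id",
    "center_x_um": "capsule center x, um",
    "center_y_um": "capsule center y, um",
    "theta_rad": "capsule orientation",
    "length_um": "true end-to-end length, um",
    "radius_um": "tube radius, um",
    "n_clusters": "true cluster count",
    "forced_empty": "true if the organelle was forced empty beyond Poisson zeros"
  },
  "truth_clusters.csv": {
    "organelle_label": "owning true organelle",
    "t_um": "position along the midline from its start, um",
    "x_um": "true cluster center x, um",
    "y_um": "true cluster center y, um"
  },
  "scores.csv": "one row per (scene, grid point): precision, recall, f1, organelle and length error summaries"
}
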