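# Complete default configuration of the synthetic monitoring study:
# n_plants tomato-like plants observed on n_days consecutive days, each
# plant-day rendered by both sensor models, prepared, measured and the
# laser (reference) vs photogrammetric (test) agreement evaluated.
# Run with:  phyto3d run --config examples/experiment.yaml --out results/

n_plants: 5            # plants in the monitoring group
n_days: 6              # consecutive observation days (growth stages)
master_seed: 0         # every random stream derives from this seed
segmentation_mode: labels   # "labels" = ground-truth organ labels (the
                            # automated stand-in for manual organ cutting);
                            # "geometric" = covariance eigenvalue classifier
n_single_leaves: 26    # single leaves sampled (size-stratified, two plants)
                       # for the single-leaf regression
truth_hull_spacing: 0.25    # mm; noise-free sampling pitch for the
                            # ground-truth convex hull (converged well below
                            # measurement tolerances at 0.25)
randomize_photo_scale: true # draw an individual arbitrary scale per cloud
write_clouds: false    # write every prepared cloud as PLY under out/clouds/

plant:                 # growth-series template (per-plant seeds derive
                       # from master_seed; "seed" here is overridden)
  n_leaves: 6          # leaves at day 0 (first two are the cotyledon pair)
  leaf_size_range: [8.0, 22.0]   # cordate half-width a in mm at day 0
  leaf_bend: 0.45      # midrib arc-bend magnitude, 0-1
  leaf_crookedness: 2.0          # normal-displacement amplitude, mm
  stem_height: 120.0   # base to cotyledon node at day 0, mm
  stem_radius: 2.5     # mm
  stem_curvature: 3.0  # lateral bow amplitude, mm
  n_branches: 4        # lateral branches at day 0
  growth_rate: 1.15    # per-day scale on stem height and leaf sizes
                       # (spans ~120 mm over the 6-day series)
  day_index: 0
  seed: 0

laser:                 # close-up triangulation line scanner (reference)
  name: laser
  target_spacing: 0.5  # mm point-to-point on the surface
  noise_sigma: 0.045   # mm, i.i.d. per point (stated sensor accuracy)
  noise_correlation_mm: 0.0
  noise_iid_sigma: 0.0
  point_budget: null   # density set by target_spacing
  scale_factor: 1.0    # metrically scaled by construction
  artifact_rate: 0.0
  artifact_offset: 1.0
  occlusion_rate: 0.0
  include_reference_frame: false

photogrammetric:       # SfM/MVS reconstruction (test method)
  name: photogrammetric
  target_spacing: 0.8  # fallback; the per-day point budget governs density
  point_budget: 30000  # overridden per day: 15k (day 0) .. 55k (day 5)
  noise_sigma: 0.5     # mm, smooth reconstruction-error field
  noise_correlation_mm: 12.0  # correlation length of that field
  noise_iid_sigma: 0.05       # mm, residual per-point matching jitter
  scale_factor: 0.004  # overridden per cloud when randomize_photo_scale
  artifact_rate: 0.05  # Bernoulli rate of white/grey border false-point
                       # clusters per leaf-border point
  artifact_offset: 1.0 # mm, offset along the local surface normal
  occlusion_rate: 0.02 # border-first point loss on small leaves
  include_reference_frame: true  # embeds the 600 mm table edge used for
                                 # metric rescaling

photo_budget_range: [15000, 55000]  # photogrammetric points day 0 -> last

prep:                  # preparation chain (scale -> crop -> outliers ->
                       # color filter -> raster [laser only])
  base_plane_z: 0.0    # crop everything below this plane (table, cube)
  crop_mode: geometric # or "labels" (oracle crop on synthetic clouds)
  crop_radius: null    # optional radial crop around the plant axis, mm
  outlier_k: 16        # neighbors for the mean-distance statistic
  outlier_n_sigma: 2.5 # removal threshold: mean + n_sigma * std
  color_filter: true   # remove white/grey (low saturation, high value)
  max_saturation: 0.15
  min_value: 0.5
  raster_spacing_mm: 0.5  # laser-path voxel rasterization pitch
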