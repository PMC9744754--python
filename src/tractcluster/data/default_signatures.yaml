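# Default per-tract morphometric signatures for the synthetic cord generator.
#
# Anchored values come from the published template statistics: axon density
# spans 78,000 axons/mm^2 (fasciculus gracilis, FG) to 168,800 axons/mm^2
# (dorsal corticospinal tract, dCST); mean axon diameter spans 1.1 um (dCST)
# to 1.35 um (dorsal column = FG/PSdc/FC); myelin thickness spans
# 0.35-0.5 um across tracts; myelin volume fraction spans 15-30%; the
# g-ratio is approximately flat at ~0.7 across tracts.
#
# Every other entry is an interpolation chosen to respect the published
# ordering (dCST much denser than all other tracts; FG and the
# lateral/ventral funiculi overlapping in density) and is a modelling
# choice, not a measured value.
#
# Standard deviations describe the pixel-to-pixel spread within a tract at
# noise_scale = 1 and are sized so that density distributions of most
# tracts overlap while dCST stays well separated.
#
# units: axon_density axons/mm^2; axon_diameter um; axon_volume_fraction
# dimensionless fraction; g_ratio dimensionless; myelin_thickness um;
# myelin_volume_fraction percent.
tracts:
  FG:
    tract_id: 1
    axon_density:           {mean: 78000.0,  sd: 16000.0}
    axon_diameter:          {mean: 1.35,     sd: 0.25}
    axon_volume_fraction:   {mean: 0.110,    sd: 0.030}
    g_ratio:                {mean: 0.70,     sd: 0.04}
    myelin_thickness:       {mean: 0.42,     sd: 0.06}
    myelin_volume_fraction: {mean: 18.0,     sd: 4.0}
  PSdc:
    tract_id: 2
    axon_density:           {mean: 85000.0,  sd: 16000.0}
    axon_diameter:          {mean: 1.35,     sd: 0.25}
    axon_volume_fraction:   {mean: 0.120,    sd: 0.030}
    g_ratio:                {mean: 0.70,     sd: 0.04}
    myelin_thickness:       {mean: 0.40,     sd: 0.06}
    myelin_volume_fraction: {mean: 17.0,     sd: 4.0}
  FC:
    tract_id: 3
    axon_density:           {mean: 105000.0, sd: 18000.0}
    axon_diameter:          {mean: 1.35,     sd: 0.25}
    axon_volume_fraction:   {mean: 0.150,    sd: 0.035}
    g_ratio:                {mean: 0.70,     sd: 0.04}
    myelin_thickness:       {mean: 0.43,     sd: 0.06}
    myelin_volume_fraction: {mean: 20.0,     sd: 4.0}
  dCST:
    tract_id: 4
    axon_density:           {mean: 168800.0, sd: 20000.0}
    axon_diameter:          {mean: 1.10,     sd: 0.20}
    axon_volume_fraction:   {mean: 0.160,    sd: 0.035}
    g_ratio:                {mean: 0.69,     sd: 0.04}
    myelin_thickness:       {mean: 0.35,     sd: 0.06}
    myelin_volume_fraction: {mean: 15.0,     sd: 4.0}
  LatC:
    tract_id: 5
    axon_density:           {mean: 90000.0,  sd: 16000.0}
    axon_diameter:          {mean: 1.20,     sd: 0.25}
    axon_volume_fraction:   {mean: 0.130,    sd: 0.030}
    g_ratio:                {mean: 0.70,     sd: 0.04}
    myelin_thickness:       {mean: 0.44,     sd: 0.06}
    myelin_volume_fraction: {mean: 21.0,     sd: 4.5}
  LSp:
    tract_id: 6
    axon_density:           {mean: 95000.0,  sd: 17000.0}
    axon_diameter:          {mean: 1.22,     sd: 0.25}
    axon_volume_fraction:   {mean: 0.135,    sd: 0.030}
    g_ratio:                {mean: 0.70,     sd: 0.04}
    myelin_thickness:       {mean: 0.45,     sd: 0.06}
    myelin_volume_fraction: {mean: 22.0,     sd: 4.5}
  RST:
    tract_id: 7
    axon_density:           {mean: 100000.0, sd: 17000.0}
    axon_diameter:          {mean: 1.25,     sd: 0.25}
    axon_volume_fraction:   {mean: 0.140,    sd: 0.030}
    g_ratio:                {mean: 0.71,     sd: 0.04}
    myelin_thickness:       {mean: 0.46,     sd: 0.06}
    myelin_volume_fraction: {mean: 24.0,     sd: 5.0}
  LF:
    tract_id: 8
    axon_density:           {mean: 82000.0,  sd: 15000.0}
    axon_diameter:          {mean: 1.30,     sd: 0.28}
    axon_volume_fraction:   {mean: 0.120,    sd: 0.030}
    g_ratio:                {mean: 0.70,     sd: 0.04}
    myelin_thickness:       {mean: 0.48,     sd: 0.06}
    myelin_volume_fraction: {mean: 27.0,     sd: 5.0}
  VF:
    tract_id: 9
    axon_density:           {mean: 80000.0,  sd: 15000.0}
    axon_diameter:          {mean: 1.32,     sd: 0.28}
    axon_volume_fraction:   {mean: 0.115,    sd: 0.030}
    g_ratio:                {mean: 0.70,     sd: 0.04}
    myelin_thickness:       {mean: 0.50,     sd: 0.06}
    myelin_volume_fraction: {mean: 30.0,     sd: 5.0}
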