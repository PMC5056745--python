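# Fast-test survey fixture: a miniature Minshan-style deployment.
# 60 stations, one warm-plus-early-winter field season, four species covering
# the nocturnal / diurnal / crepuscular-nocturnal / arrhythmic archetypes,
# two focal pairs (one avoiding, gamma=0.6; one independent, gamma=1.0).
n_stations: 60
window_start: "2013-03-01"
window_end: "2013-12-20"
deployment_days_min: 28.0
deployment_days_max: 42.0
centroid_lat: 32.9
centroid_lon: 104.1
coord_jitter_deg: 0.35
tz_hours: 8.0
p_fast_camera: 0.6
duplicate_prob: 0.25
seed: 20130301
species:
  - name: civet
    psi: 0.55
    daily_rate: 0.10
    diel_means_h: [22.0, 4.0]
    diel_kappas: [3.0, 3.0]
    diel_weights: [0.5, 0.5]
    # winter dormancy: no December-February detections
    monthly_multipliers: [0.0, 0.0, 0.6, 0.8, 1.0, 1.2, 1.4, 1.4, 1.2, 0.8, 0.5, 0.0]
  - name: badger
    psi: 0.50
    daily_rate: 0.12
    diel_means_h: [21.0, 5.5]
    diel_kappas: [2.0, 2.5]
    diel_weights: [0.6, 0.4]
    monthly_multipliers: [0.1, 0.1, 0.6, 0.8, 1.0, 1.3, 1.4, 1.3, 1.2, 0.8, 0.4, 0.1]
  - name: marten
    psi: 0.45
    daily_rate: 0.08
    diel_means_h: [12.0]
    diel_kappas: [2.5]
    diel_weights: [1.0]
    monthly_multipliers: [1.4, 1.2, 1.0, 0.9, 0.9, 0.9, 1.0, 1.0, 1.0, 1.0, 1.1, 1.5]
  - name: weasel
    psi: 0.60
    daily_rate: 0.12
    diel_means_h: [12.0]
    diel_kappas: [0.2]
    diel_weights: [1.0]
    monthly_multipliers: [1.2, 1.2, 0.9, 0.8, 0.8, 0.9, 1.3, 1.4, 1.3, 0.8, 0.9, 1.2]
pairs:
  - species_a: civet
    species_b: badger
    gamma: 0.6
  - species_a: marten
    species_b: weasel
    gamma: 1.0
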