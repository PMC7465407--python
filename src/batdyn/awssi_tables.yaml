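# Default AWSSI daily point tables (metric adaptation).
#
# Temperature points are earned separately for the daily maximum and daily
# minimum; a day earns the points of the coldest band it reaches.  Snow
# points are earned separately for daily snowfall and standing snow depth.
# Band edges are metric conversions of the conventional Fahrenheit / inch
# scoring bands (5 F ~ 2.8 C temperature steps, 1 in = 2.54 cm).
#
# Encoding: temperature bands are [upper_bound_celsius, points] pairs, a
# value earns the points of the smallest bound it is <=; snow bands are
# [lower_bound_cm, points] pairs, a value earns the points of the largest
# bound it is >=.  Bands must be listed monotonically.

tmax_points:
  - [0.0, 1]
  - [-3.9, 2]
  - [-6.7, 3]
  - [-9.4, 4]
  - [-12.2, 5]
  - [-15.0, 6]
  - [-17.8, 7]
  - [-20.6, 8]
  - [-23.3, 9]
  - [-26.1, 10]
  - [-28.9, 11]
  - [-31.7, 12]
  - [-34.4, 13]

tmin_points:
  - [0.0, 1]
  - [-3.9, 2]
  - [-6.7, 3]
  - [-9.4, 4]
  - [-12.2, 5]
  - [-15.0, 6]
  - [-17.8, 7]
  - [-20.6, 8]
  - [-23.3, 9]
  - [-26.1, 10]
  - [-28.9, 11]
  - [-31.7, 12]
  - [-34.4, 13]
  - [-37.2, 14]
  - [-40.0, 15]

snowfall_points:
  - [0.25, 1]
  - [2.5, 2]
  - [5.1, 3]
  - [7.6, 4]
  - [10.2, 5]
  - [12.7, 6]
  - [15.2, 7]
  - [17.8, 8]
  - [20.3, 9]
  - [22.9, 10]
  - [25.4, 12]
  - [30.5, 15]
  - [38.1, 18]
  - [45.7, 22]
  - [61.0, 26]

snow_depth_points:
  - [2.5, 1]
  - [7.6, 2]
  - [12.7, 3]
  - [17.8, 4]
  - [22.9, 5]
  - [30.5, 6]
  - [38.1, 7]
  - [45.7, 8]
  - [61.0, 9]
  - [91.4, 10]

# Snowfall estimation from liquid precipitation on cold days.
snow_rules:
  # a day is "snow-capable" when its mean temperature ((tmax+tmin)/2) <= this
  warm_day_mean_celsius: 0.0
  # conventional snow-to-liquid volume ratio
  snow_to_liquid_ratio: 10.0
  # cm of standing snow lost per positive degree-day (carry-forward fill)
  melt_cm_per_degree_day: 2.0
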