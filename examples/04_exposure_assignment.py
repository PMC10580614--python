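"""Assigning gridded exposures to urban polygons and rural points.

Urban localities get a population-weighted average over the cells they
intersect; rural localities get the containing cell's value.
"""

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from lagcrossover import (
    ExposureFields, Grid, Locality, build_locality_series,
    point_extract, population_weighted_extract,
)

# the hand-checkable weighted mean: cells at 10 and 20 with population
# weights 100 and 300 -> (10*100 + 20*300) / 400 = 17.5
v = population_weighted_extract(
    {0: 10.0, 1: 20.0}, {0: 100.0, 1: 300.0}, {0: 1.0, 1: 1.0}
)
print(f"population-weighted mean: {v}")

grid = Grid(nrows=2, ncols=2)
dates = pd.date_range("2004-01-01", periods=3, freq="D")
pm = np.array([[10.0, 20.0, 30.0, 40.0]] * 3)
fields = ExposureFields(grid=grid, dates=dates, pm=pm, temp=np.full((3, 4), 15.0))

localities = [
    Locality("U1", True, box(0, 0, 2, 1)),   # spans cells 0 and 1
    Locality("R1", False, Point(0.4, 1.6)),  # inside cell 2
]
series = build_locality_series(fields, localities, {0: 100.0, 1: 300.0, 2: 50.0, 3: 50.0})
print(series.to_frame().to_string(index=False))
# U1 = 17.5 every day (weighted over cells 0,1); R1 = 30.0 (cell 2)
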