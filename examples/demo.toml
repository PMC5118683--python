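# Demo scenario: a 200x200 pixel landscape (50 km side at 250 m pixels)
# over 13 annual maps, with three localized conversion processes on a
# grassland background and 2% per-pixel classification noise.

grid_shape = [200, 200]
years = [2001, 2002, 2003, 2004, 2005, 2006, 2007, 2008, 2009, 2010, 2011, 2012, 2013]
pixel_size = 250.0
noise_rate = 0.02
block_size = 10
seed = 42

[regions]
# [row0, row1, col0, col1] half-open pixel rectangles
urban_fringe = [20, 100, 20, 100]
reclamation = [20, 100, 120, 180]
mountain = [120, 180, 20, 180]

[region_initial]
urban_fringe = { AGRI = 0.70, URBN = 0.20, GRAS = 0.10 }
reclamation = { GRAS = 0.80, AGRI = 0.20 }
mountain = { OPSH = 0.40, CLSH = 0.30, DBLE = 0.20, GRAS = 0.10 }

[background]
GRAS = 0.70
BARE = 0.20
WATR = 0.10

[[transitions]]
# urban expansion consuming cropland around existing urban patches
region = "urban_fringe"
from = "AGRI"
to = "URBN"
rate = 0.012
mode = "clustered"

[[transitions]]
# agricultural reclamation of grassland
region = "reclamation"
from = "GRAS"
to = "AGRI"
rate = 0.015
mode = "random"

[[transitions]]
# shrubland succeeding to forest in the uplands
region = "mountain"
from = "CLSH"
to = "DBLE"
rate = 0.010
mode = "clustered"
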