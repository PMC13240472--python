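# Keyword dictionary mapping isolation-source / geographic-location text to
# the seven marine biomes (plus sub-categories for coastal and seawater).
#
# Best-effort reconstruction of a manual curation step: matching is
# case-insensitive, longest keyword wins, no match -> excluded. Seawater
# depth sub-zones are resolved from the depth covariate, not from keywords.
keywords:
  "hydrothermal":        {biome: hydrothermal_vent}
  "hydrothermal vent":   {biome: hydrothermal_vent}
  "black smoker":        {biome: hydrothermal_vent}
  "vent chimney":        {biome: hydrothermal_vent}
  "vent fluid":          {biome: hydrothermal_vent}
  "coastal":             {biome: coastal, sub: unspecified}
  "coastal water":       {biome: coastal, sub: coastal_water}
  "coastal sediment":    {biome: coastal, sub: coastal_sediment}
  "estuary":             {biome: coastal, sub: coastal_water}
  "intertidal":          {biome: coastal, sub: coastal_sediment}
  "seawater":            {biome: seawater}
  "open ocean":          {biome: seawater}
  "water column":        {biome: seawater}
  "brine pool":          {biome: seawater}
  "marine sediment":     {biome: sediment}
  "sediment":            {biome: sediment}
  "cold seep":           {biome: sediment}
  "mud volcano":         {biome: sediment}
  "subseafloor":         {biome: sediment}
  "coral":               {biome: host_associated}
  "sponge":              {biome: host_associated}
  "gutless worm":        {biome: host_associated}
  "marine worm":         {biome: host_associated}
  "diatom":              {biome: host_associated}
  "dinoflagellate":      {biome: host_associated}
  "phycosphere":         {biome: host_associated}
  "algae":               {biome: host_associated}
  "symbiont":            {biome: host_associated}
  "oil field":           {biome: oil_field}
  "oil reservoir":       {biome: oil_field}
  "petroleum":           {biome: oil_field}
  "produced water":      {biome: oil_field}
  "saltern":             {biome: solar_saltern}
  "solar saltern":       {biome: solar_saltern}
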