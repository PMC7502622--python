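corine_code,pooled_class
111,built_up
112,built_up
121,built_up
122,other
123,other
124,other
131,other
132,other
133,other
141,other
142,other
211,cropland
212,cropland
213,cropland
221,other
222,other
231,grassland
241,other
242,other
243,other
244,other
311,deciduous_forest
312,coniferous_forest
313,deciduous_forest
321,grassland
322,other
323,other
324,other
331,other
332,other
333,other
334,other
335,other
411,wetland
412,wetland
421,other
422,other
423,other
511,open_water
512,open_water
521,other
522,other
523,other
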