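{"type": "FeatureCollection", "features": [{"type": "Feature", "properties": {"unit_id": "west", "name": "West"}, "geometry": {"type": "Polygon", "coordinates": [[[10.0, 0.0], [10.0, 20.0], [0.0, 20.0], [0.0, 0.0], [10.0, 0.0]]]}}, {"type": "Feature", "properties": {"unit_id": "east", "name": "East"}, "geometry": {"type": "Polygon", "coordinates": [[[20.0, 0.0], [20.0, 20.0], [10.0, 20.0], [10.0, 0.0], [20.0, 0.0]]]}}]}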