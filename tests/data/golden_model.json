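{
 "points": [
  {
   "atom_index": 5,
   "enabled": true,
   "name": "HydrogenDonor",
   "normalized_score": 1.0,
   "partner": "A",
   "radius": 1.0,
   "raw_score": 50.0,
   "residue_index": 0,
   "vector": [
    {
     "x": 0.0,
     "y": 0.0,
     "z": 1.0
    }
   ],
   "vector_on": 1,
   "x": 1.0,
   "y": 2.0,
   "z": 3.0
  },
  {
   "enabled": true,
   "name": "Aromatic",
   "normalized_score": 1.0,
   "partner": "B",
   "radius": 1.0,
   "raw_score": 0.5,
   "residue_index": 1,
   "vector": [
    {
     "x": 0.0,
     "y": 1.0,
     "z": 0.0
    },
    {
     "x": 0.0,
     "y": -1.0,
     "z": 0.0
    }
   ],
   "vector_on": 1,
   "x": 4.0,
   "y": 5.0,
   "z": 6.0
  },
  {
   "enabled": true,
   "name": "Hydrophobic",
   "normalized_score": 1.0,
   "partner": "B",
   "radius": 1.0,
   "raw_score": 0.4,
   "residue_index": 2,
   "x": 7.0,
   "y": 8.0,
   "z": 9.0
  },
  {
   "enabled": true,
   "name": "ExclusionSphere",
   "radius": 1.0,
   "x": 0.0,
   "y": 0.0,
   "z": 0.0
  },
  {
   "enabled": true,
   "name": "ExclusionSphere",
   "radius": 1.0,
   "x": 10.0,
   "y": 0.0,
   "z": 0.0
  }
 ]
}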