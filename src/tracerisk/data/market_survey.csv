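market,body_part,element,mean_conc_mg_kg_fw,sd_mg_kg,n,bdl
Uttara,muscle,Pb,0.445,0.02,3,false
Gabtoli,muscle,Pb,0.734,0.1,3,false
Badda,muscle,Pb,0.881,0.09,3,false
Karwan Bazar,muscle,Pb,0.679,0.1,3,false
Mohammadpur,muscle,Pb,0.656,0.2,3,false
Rayer Bazar,muscle,Pb,0.547,0.1,3,false
Uttara,liver,Pb,0.391,0.1,3,false
Gabtoli,liver,Pb,0.552,0.1,3,false
Badda,liver,Pb,0.772,0.2,3,false
Karwan Bazar,liver,Pb,0.486,0.3,3,false
Mohammadpur,liver,Pb,,,3,true
Rayer Bazar,liver,Pb,0.762,0.7,3,false
Uttara,gizzard,Pb,0.555,0.1,3,false
Gabtoli,gizzard,Pb,0.737,0.1,3,false
Badda,gizzard,Pb,0.881,0.3,3,false
Karwan Bazar,gizzard,Pb,0.655,0.2,3,false
Mohammadpur,gizzard,Pb,0.645,0.1,3,false
Rayer Bazar,gizzard,Pb,1.012,0.2,3,false
Uttara,heart,Pb,0.506,0.3,3,false
Gabtoli,heart,Pb,0.328,0.2,3,false
Badda,heart,Pb,1.007,0.4,3,false
Karwan Bazar,heart,Pb,0.689,0.2,3,false
Mohammadpur,heart,Pb,0.537,0.0,3,false
Rayer Bazar,heart,Pb,1.104,0.3,3,false
Uttara,kidney,Pb,1.253,0.3,3,false
Gabtoli,kidney,Pb,0.650,0.2,3,false
Badda,kidney,Pb,0.906,0.5,3,false
Karwan Bazar,kidney,Pb,1.607,1.3,3,false
Mohammadpur,kidney,Pb,0.726,0.1,3,false
Rayer Bazar,kidney,Pb,0.844,0.1,3,false
Uttara,brain,Pb,3.903,0.3,3,false
Gabtoli,brain,Pb,3.510,0.7,3,false
Badda,brain,Pb,4.943,0.99,3,false
Karwan Bazar,brain,Pb,3.964,1.1,3,false
Mohammadpur,brain,Pb,2.019,0.5,3,false
Rayer Bazar,brain,Pb,2.382,0.9,3,false
Uttara,muscle,Cd,0.035,0.0,3,false
Gabtoli,muscle,Cd,,,3,true
Badda,muscle,Cd,,,3,true
Karwan Bazar,muscle,Cd,0.034,0.0,3,false
Mohammadpur,muscle,Cd,0.023,0.0,3,false
Rayer Bazar,muscle,Cd,0.037,0.0,3,false
Uttara,liver,Cd,0.058,0.1,3,false
Gabtoli,liver,Cd,0.069,0.0,3,false
Badda,liver,Cd,0.078,0.0,3,false
Karwan Bazar,liver,Cd,0.102,0.0,3,false
Mohammadpur,liver,Cd,0.107,0.0,3,false
Rayer Bazar,liver,Cd,0.075,0.0,3,false
Uttara,gizzard,Cd,,,3,true
Gabtoli,gizzard,Cd,,,3,true
Badda,gizzard,Cd,0.007,0.0,3,false
Karwan Bazar,gizzard,Cd,0.049,0.0,3,false
Mohammadpur,gizzard,Cd,0.047,0.0,3,false
Rayer Bazar,gizzard,Cd,0.084,0.0,3,false
Uttara,heart,Cd,,,3,true
Gabtoli,heart,Cd,,,3,true
Badda,heart,Cd,,,3,true
Karwan Bazar,heart,Cd,0.009,0.0,3,false
Mohammadpur,heart,Cd,0.002,0.0,3,false
Rayer Bazar,heart,Cd,,,3,true
Uttara,kidney,Cd,0.016,0.0,3,false
Gabtoli,kidney,Cd,0.004,0.0,3,false
Badda,kidney,Cd,0.032,0.0,3,false
Karwan Bazar,kidney,Cd,0.006,0.0,3,false
Mohammadpur,kidney,Cd,0.012,0.0,3,false
Rayer Bazar,kidney,Cd,0.017,0.0,3,false
Uttara,brain,Cd,,,3,true
Gabtoli,brain,Cd,0.037,0.0,3,false
Badda,brain,Cd,0.041,0.0,3,false
Karwan Bazar,brain,Cd,,,3,true
Mohammadpur,brain,Cd,,,3,true
Rayer Bazar,brain,Cd,,,3,true
Uttara,muscle,Cr,,,3,true
Gabtoli,muscle,Cr,,,3,true
Badda,muscle,Cr,,,3,true
Karwan Bazar,muscle,Cr,0.281,0.02,3,false
Mohammadpur,muscle,Cr,0.826,0.0,3,false
Rayer Bazar,muscle,Cr,,,3,true
Uttara,liver,Cr,0.550,0.0,3,false
Gabtoli,liver,Cr,0.920,0.0,3,false
Badda,liver,Cr,,,3,true
Karwan Bazar,liver,Cr,0.473,0.0,3,false
Mohammadpur,liver,Cr,,,3,true
Rayer Bazar,liver,Cr,,,3,true
Uttara,gizzard,Cr,0.223,0.05,3,false
Gabtoli,gizzard,Cr,,,3,true
Badda,gizzard,Cr,,,3,true
Karwan Bazar,gizzard,Cr,,,3,true
Mohammadpur,gizzard,Cr,,,3,true
Rayer Bazar,gizzard,Cr,,,3,true
Uttara,heart,Cr,,,3,true
Gabtoli,heart,Cr,,,3,true
Badda,heart,Cr,,,3,true
Karwan Bazar,heart,Cr,0.286,0.0,3,false
Mohammadpur,heart,Cr,0.006,0.0,3,false
Rayer Bazar,heart,Cr,0.364,0.0,3,false
Uttara,kidney,Cr,,,3,true
Gabtoli,kidney,Cr,0.147,0.0,3,false
Badda,kidney,Cr,,,3,true
Karwan Bazar,kidney,Cr,0.053,0.0,3,false
Mohammadpur,kidney,Cr,,,3,true
Rayer Bazar,kidney,Cr,,,3,true
Uttara,brain,Cr,0.569,0.0,3,false
Gabtoli,brain,Cr,0.944,0.4,3,false
Badda,brain,Cr,1.006,0.3,3,false
Karwan Bazar,brain,Cr,0.777,0.0,3,false
Mohammadpur,brain,Cr,,,3,true
Rayer Bazar,brain,Cr,0.569,0.0,3,false
Uttara,muscle,Fe,4.682,1.2,3,false
Gabtoli,muscle,Fe,5.154,5.0,3,false
Badda,muscle,Fe,2.701,3.8,3,false
Karwan Bazar,muscle,Fe,5.576,2.6,3,false
Mohammadpur,muscle,Fe,10.277,1.6,3,false
Rayer Bazar,muscle,Fe,7.058,1.2,3,false
Uttara,liver,Fe,76.879,23.8,3,false
Gabtoli,liver,Fe,56.254,16.4,3,false
Badda,liver,Fe,52.936,14.6,3,false
Karwan Bazar,liver,Fe,39.967,6.4,3,false
Mohammadpur,liver,Fe,92.319,48.8,3,false
Rayer Bazar,liver,Fe,77.172,12.2,3,false
Uttara,gizzard,Fe,20.524,5.5,3,false
Gabtoli,gizzard,Fe,19.152,5.6,3,false
Badda,gizzard,Fe,17.281,4.8,3,false
Karwan Bazar,gizzard,Fe,22.663,3.3,3,false
Mohammadpur,gizzard,Fe,18.262,8.3,3,false
Rayer Bazar,gizzard,Fe,37.107,18.6,3,false
Uttara,heart,Fe,33.449,12.1,3,false
Gabtoli,heart,Fe,14.727,7.4,3,false
Badda,heart,Fe,28.818,5.7,3,false
Karwan Bazar,heart,Fe,28.502,0.9,3,false
Mohammadpur,heart,Fe,26.364,1.1,3,false
Rayer Bazar,heart,Fe,29.887,0.8,3,false
Uttara,kidney,Fe,43.947,13.2,3,false
Gabtoli,kidney,Fe,53.432,28.4,3,false
Badda,kidney,Fe,32.727,6.9,3,false
Karwan Bazar,kidney,Fe,45.029,15.4,3,false
Mohammadpur,kidney,Fe,44.656,8.2,3,false
Rayer Bazar,kidney,Fe,42.518,5.6,3,false
Uttara,brain,Fe,79.619,57.0,3,false
Gabtoli,brain,Fe,25.490,5.5,3,false
Badda,brain,Fe,26.996,1.6,3,false
Karwan Bazar,brain,Fe,27.601,8.5,3,false
Mohammadpur,brain,Fe,41.239,37.9,3,false
Rayer Bazar,brain,Fe,25.526,12.8,3,false
Uttara,muscle,Cu,0.141,0.03,3,false
Gabtoli,muscle,Cu,0.158,0.0,3,false
Badda,muscle,Cu,0.068,0.01,3,false
Karwan Bazar,muscle,Cu,0.174,0.1,3,false
Mohammadpur,muscle,Cu,0.325,0.1,3,false
Rayer Bazar,muscle,Cu,0.228,0.0,3,false
Uttara,liver,Cu,2.380,0.4,3,false
Gabtoli,liver,Cu,2.278,0.3,3,false
Badda,liver,Cu,2.980,1.3,3,false
Karwan Bazar,liver,Cu,2.373,0.6,3,false
Mohammadpur,liver,Cu,1.926,0.3,3,false
Rayer Bazar,liver,Cu,2.368,0.3,3,false
Uttara,gizzard,Cu,0.557,0.2,3,false
Gabtoli,gizzard,Cu,0.501,0.1,3,false
Badda,gizzard,Cu,0.429,0.1,3,false
Karwan Bazar,gizzard,Cu,0.470,0.2,3,false
Mohammadpur,gizzard,Cu,0.315,0.2,3,false
Rayer Bazar,gizzard,Cu,0.543,0.2,3,false
Uttara,heart,Cu,2.785,0.5,3,false
Gabtoli,heart,Cu,1.281,0.4,3,false
Badda,heart,Cu,2.409,0.7,3,false
Karwan Bazar,heart,Cu,2.696,0.3,3,false
Mohammadpur,heart,Cu,2.631,0.2,3,false
Rayer Bazar,heart,Cu,2.871,0.4,3,false
Uttara,kidney,Cu,2.303,0.6,3,false
Gabtoli,kidney,Cu,1.421,0.6,3,false
Badda,kidney,Cu,1.903,0.2,3,false
Karwan Bazar,kidney,Cu,2.440,0.4,3,false
Mohammadpur,kidney,Cu,1.931,0.5,3,false
Rayer Bazar,kidney,Cu,2.134,0.1,3,false
Uttara,brain,Cu,3.454,2.7,3,false
Gabtoli,brain,Cu,2.930,0.3,3,false
Badda,brain,Cu,3.112,0.7,3,false
Karwan Bazar,brain,Cu,2.793,0.9,3,false
Mohammadpur,brain,Cu,2.387,0.5,3,false
Rayer Bazar,brain,Cu,2.579,0.6,3,false
Uttara,muscle,Zn,4.452,0.6,3,false
Gabtoli,muscle,Zn,4.530,0.6,3,false
Badda,muscle,Zn,5.576,0.8,3,false
Karwan Bazar,muscle,Zn,7.953,6.8,3,false
Mohammadpur,muscle,Zn,6.078,0.9,3,false
Rayer Bazar,muscle,Zn,6.311,1.2,3,false
Uttara,liver,Zn,16.045,2.6,3,false
Gabtoli,liver,Zn,18.301,1.5,3,false
Badda,liver,Zn,23.545,11.1,3,false
Karwan Bazar,liver,Zn,16.986,0.6,3,false
Mohammadpur,liver,Zn,17.453,3.5,3,false
Rayer Bazar,liver,Zn,23.755,4.3,3,false
Uttara,gizzard,Zn,16.599,2.9,3,false
Gabtoli,gizzard,Zn,18.010,0.7,3,false
Badda,gizzard,Zn,16.200,2.8,3,false
Karwan Bazar,gizzard,Zn,16.455,2.1,3,false
Mohammadpur,gizzard,Zn,11.786,5.3,3,false
Rayer Bazar,gizzard,Zn,20.217,1.6,3,false
Uttara,heart,Zn,16.625,1.2,3,false
Gabtoli,heart,Zn,7.737,2.6,3,false
Badda,heart,Zn,16.601,3.3,3,false
Karwan Bazar,heart,Zn,16.279,0.6,3,false
Mohammadpur,heart,Zn,15.508,0.2,3,false
Rayer Bazar,heart,Zn,17.155,2.2,3,false
Uttara,kidney,Zn,16.131,5.3,3,false
Gabtoli,kidney,Zn,10.245,4.2,3,false
Badda,kidney,Zn,14.063,2.6,3,false
Karwan Bazar,kidney,Zn,16.432,2.5,3,false
Mohammadpur,kidney,Zn,15.524,2.9,3,false
Rayer Bazar,kidney,Zn,15.095,0.6,3,false
Uttara,brain,Zn,19.491,11.6,3,false
Gabtoli,brain,Zn,13.107,1.3,3,false
Badda,brain,Zn,15.054,1.7,3,false
Karwan Bazar,brain,Zn,13.117,0.6,3,false
Mohammadpur,brain,Zn,12.466,1.9,3,false
Rayer Bazar,brain,Zn,10.492,0.95,3,false
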