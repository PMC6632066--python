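parameter,attribute,S,P,D,justification
filling level,carr index,5,7,3,Amount of mixture noticeably affects flowability
filling level,drug content,7,7,7,Filling level directly governs mixture homogeneity
filling level,cu,7,7,7,Filling level directly governs content uniformity
rotational speed,carr index,5,7,3,Rotational speed noticeably affects flowability
rotational speed,drug content,7,7,7,Rotational speed directly governs mixture homogeneity
rotational speed,cu,7,7,7,Rotational speed directly governs content uniformity
order of input,carr index,3,3,3,Order of input has limited effect on the attributes
order of input,drug content,3,3,7,Order of input has limited effect on drug content
order of input,cu,3,3,7,Order of input has limited effect on content uniformity
blending time,carr index,5,7,3,Blending time noticeably affects flowability
blending time,drug content,7,7,7,Blending time directly governs mixture homogeneity
blending time,cu,7,7,7,Blending time directly governs content uniformity
manufacturing environment,carr index,3,3,3,Environment held at constant temperature and humidity
manufacturing environment,drug content,3,3,7,Environment held at constant temperature and humidity
manufacturing environment,cu,3,3,7,Environment held at constant temperature and humidity
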