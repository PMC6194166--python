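# Explanation template bank. One template per line: "<locality>\t<template>".
# Placeholders: {cat} = reported category, {other} = the other category,
# {region} = a named local region of the embryo.
# Lines starting with '#' and blank lines are ignored.
local	Shading on the {region} of {cat} is darker and sharper than on {other}.
local	The {region} has a shadowy triangular notch for {cat}.
local	{cat} shows a light, shallow groove along the {region}; {other} does not.
local	Look at the {region}: it bulges outward for {cat} and stays flat for {other}.
local	The shadow just beneath the {region} is crisp for {cat} and diffuse for {other}.
local	{cat} has a small dimple on the {region} that {other} lacks.
global	{cat} looks smoother and rounder overall than {other}.
global	{cat} is generally darker and curvier.
global	The overall shading of {cat} is milder, more even than {other}.
global	{cat} has a harsher, lumpier look all over.
global	The silhouette of {cat} feels more elongated on the whole.
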