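category,divisions,parts
combined,3,1&3
combined,4,1&4
combined,4,1&3&4
combined,4,1&2&4
combined,5,1&5
combined,5,1&2&5
combined,5,1&4&5
combined,5,1&2&4&5
combined,5,1&2&3&5
combined,5,1&3&4&5
combined,5,1&2&3&4&5
beginning,3,1
beginning,4,1
beginning,4,2
beginning,4,1&2
beginning,5,1
beginning,5,2
beginning,5,3
beginning,5,1&2
beginning,5,1&3
beginning,5,2&3
beginning,5,1&2&3
end,3,3
end,4,3
end,4,4
end,4,3&4
end,5,3
end,5,4
end,5,5
end,5,3&4
end,5,3&5
end,5,4&5
end,5,3&4&5
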